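# Methods

Model definitions, conventions, and numerical choices behind `dmrgfq`.
All energies are in Hartree and lengths in Bohr internally; user-facing
geometry I/O is in Ångström and excitation energies are reported in eV
(1 Ha = 27.211386245988 eV, 1 Å = 1.8897261254578281 Bohr).

## Fluctuating-charge (FQ) environment

Each environment atom carries an electronegativity χ_i and hardness η_i.
For charges q the classical energy is

    E_FQ(q) = Σ_i q_i χ_i + ½ Σ_ij q_i T_ij q_j

with the Ohno-damped Coulomb kernel

    T_ii = η_i,      T_ij = [ r_ij² + ((η_i+η_j)/2)⁻² ]^(−1/2)   (i ≠ j),

which tends to 1/r at long range and to the average hardness at coincidence,
preventing the polarization catastrophe. Charges minimize
E_FQ(q) + q·V^ext subject to fixed total charge per molecule; stationarity
gives the bordered symmetric linear system

    [ T   C ] [ q ]   [ −χ − V^ext ]
    [ Cᵀ  0 ] [ λ ] = [     Q      ]

with C the group indicator matrix and λ one Lagrange multiplier per
molecule. At the solution the effective electronegativity
χ_i + (Tq)_i + V_i is uniform (= −λ) within each molecule
(electronegativity equalization). The solve is validated against a
brute-force SLSQP constrained minimizer to 1e-10 per charge.

## QM region and embedding

A small McMurchie–Davidson Gaussian backend supplies overlap, kinetic,
nuclear-attraction, two-electron, and point-charge potential integrals;
RHF provides starting orbitals. The active-space Hamiltonian folds a closed
inactive shell into a core Fock operator plus a scalar core energy.

The QM↔FQ coupling is purely electrostatic. With V^FQ_i(ao) the AO matrix of
the potential at FQ site i and V^nuc_i the solute-nuclear potential there,
fixed charges q dress the one-electron Hamiltonian at the AO level:

    h_eff = h − Σ_i q_i V^FQ_i(ao),       scalar shift  Σ_i q_i V^nuc_i,

so that ⟨H_eff⟩ − ⟨H⟩ = q·V(D) exactly, where V(D) is the total solute
electrostatic potential at the FQ sites for density D. The reported
decomposition E_total = E_DMRG + E_FQ + E_int is exact by construction
(E_DMRG uses the bare integrals; E_int = q·V(D)).

## DMRG engine

The active-space Hamiltonian is mapped to spin orbitals (Jordan–Wigner
strings) and assembled as an MPO by summing product-operator strings with
exact SVD compression (relative cutoff 1e-13). Ground states come from
two-site sweeps: each local 2-site problem is solved with Davidson (dense
fallback for ≤256 local dimensions), followed by SVD truncation to the bond
dimension M of the current schedule stage.

Sector targeting: the initial MPS is built sector-pure in (N, 2Sz); since H
commutes with N and Sz dense sweeps preserve the sector, and a quadratic
penalty MPO μ[(N̂−N₀)² + (Ŝz−Sz₀)²] with μ = 10 is added as a safety net.
Singlet targeting adds μ·Ŝ² to the same penalty MPO. Penalties act only on
the sweep objective; every reported energy is reassembled from the 1- and
2-RDMs with the physical integrals, so the penalties cannot bias results.

Excited states are computed state-specifically as the lowest state
orthogonal to the converged ground MPS (overlap-projected local problems),
each with its own orbitals and (in solution) its own charges.

RDMs use the chemist convention
P_pqrs = Σ_στ ⟨c†_pσ c†_rτ c_sτ c_qσ⟩ with E = Σ h_pq D_pq +
½ Σ g_pqrs P_pqrs + E_core, and satisfy Σ_r P_pqrr = (N−1) D_pq.
An optional Fiedler ordering of the exchange-weight graph reduces bond
dimensions for chain-like integrals; RDMs are permuted back to the original
orbital labels.

## Orbital optimization

With full-space densities γ, d (closed inactive shell embedded analytically:
d_ijkl = 4δ_ijδ_kl − 2δ_ilδ_jk, d_tuii = d_iitu = 2D_tu,
d_tiju = d_ituj = −δ_ij D_tu, active block = P), the generalized Fock matrix
is F_mn = Σ_q γ_mq h_nq + Σ_qrs d_mqrs (nq|rs) and the gradient of the
energy under C ← C·exp(A) is dE/dA_rs = 2(F_sr − F_rs), restricted to the
non-redundant pairs (inactive–active, inactive–virtual, active–virtual).
Optimization alternates the active-space solver (DMRG) with an L-BFGS-B
minimization of the fixed-density energy over rotation parameters bounded by
a trust radius (halved on rejected steps). Convergence is declared on the
gradient norm; the macro energy trace is non-increasing. The gradient is
verified against central finite differences of the fully re-solved total
energy (step 1e-5) to better than 1e-6, with and without embedding charges,
and full optimizations agree with an independent CASSCF minimizer to 1e-8.

## Self-consistent DMRG/FQ loop

For each electronic state: RHF (or supplied) orbitals → bare-Hamiltonian
MPS and density D⁰ → initial charges from solve_fq with V(D⁰) → iterate
{orbital/MPS cycle at fixed q; charge update from the new density, with
optional linear damping} until |ΔE_total| < 1e-8 and max|Δq| < 1e-6.
Repeated energy increases engage damping α = 0.5 automatically. At
convergence the total energy is stationary with respect to feasible
(charge-conserving) charge perturbations to first order, and moving the
environment 10⁴ Bohr away reproduces the gas-phase energy plus the
isolated-environment FQ energy to 1e-8.

`embedding` modes: `"polarizable"` (full loop), `"frozen"` (charges fixed at
their isolated or supplied values), `"none"` (gas phase).

## Snapshot pipeline

Droplet rule: a solvent molecule is kept if any of its atoms lies within the
radius of the nearest solute atom (whole molecules only; a center-of-mass
rule is also available). Each retained frame becomes a QM solute + FQ shell
and runs the state-specific ground and excited solver; the vertical gap is
(E_ES − E_GS)·27.2114 eV, with negative gaps flagged as root flips.
Ensemble statistics: mean, median, histogram mode (default bin 0.05 eV),
spread (max−min), and standard error stdev/√n; convergence is monitored by
prefix means at frame-count checkpoints. The solvatochromic shift is
solution-phase minus gas-phase mean (positive = blue shift).

## Design decisions and limitations

- Dense MPS/MPO tensors (no block-sparse quantum-number machinery): sector
  purity plus penalties delivers the same results at fixture scale at far
  lower implementation risk; both paths are tested to agree.
- Minimal integral backend (STO-3G class) instead of an external quantum
  chemistry dependency; accuracy is set by the basis, not the solver, and
  every solver layer is oracle-tested independently of the integrals.
- State-specific (not state-averaged) orbitals and charges; near-degenerate
  states can in principle root-flip, which the pipeline flags rather than
  hides.
- CASSCF is non-convex: convergence is to a stationary basin. Starting
  orbitals far from a minimum may converge to a different local solution
  with a perfectly small gradient.
- The orbital macro-iteration is first-order (gradient only) and converges
  linearly; it is sized for fixture-scale active spaces, not production
  (24,22)-class calculations.
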