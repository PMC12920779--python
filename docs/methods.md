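# Methods

## Model

### Local baseline

The host network is an invariant continuous-filter convolution MPNN
(SchNet-family). Atomic numbers index a learnable embedding table
(h ∈ ℝ^F, default F = 64). Each of T = 2 interaction layers computes
messages m_i = Σ_j W_filt(rbf(d_ij)) ⊙ (W₁h_j) · f_cut(d_ij) and applies a
residual update h ← h + MLP(m). The radial basis uses n_rbf = 20 Gaussians
with centers equally spaced on [0, cutoff] and γ = 1/(2Δc²); the cutoff
function is ½(cos(πd/r_c)+1), C¹ at r_c = 5 Å. All MLPs use shifted
softplus (ln(1+eˣ) − ln 2): a C^∞ activation is required for continuous
forces. Message pooling is a sum (not a mean) so energies are
size-extensive. The energy readout is an atom-wise MLP (F → F/2 → 1) plus a
learnable per-species reference energy, summed over atoms.

The baseline is deliberately invariant (distances only); the virtual-node
block is model-agnostic and would attach to an equivariant host the same
way, but the invariant host is the smallest one that exposes every
property being tested.

A fixed short-range repulsive prior k·(r₀/r)¹²·f_cut(r) (k = 0.05 kcal/mol,
r₀ = 2 Å, summed over neighbor-list pairs) sits under the network, which
learns the residual — the delta-learning baseline common in interatomic
potentials. Its purpose is a guaranteed physical wall below the distances
the training data samples: a network alone extrapolates arbitrarily there,
and molecular dynamics at 300 K reaches compressions that narrow-jitter
training sets never cover. At sampled geometries the prior contributes
fractions of a kcal/mol and the network absorbs it; it is multiplied by the
cosine cutoff so energies remain C¹ everywhere, and it can be disabled per
model (`repulsive_prior=False`).

### Virtual-node attention block

After every interaction layer, K = 4 master nodes (H = 8 heads, head width
D_h = F/H = 8) run one aggregation–broadcast cycle (equations in the
README). Design choices that were genuinely open, and how they were fixed:

- **Additive (GATv2-style) scoring** with LeakyReLU slope 0.2, separate
  score vectors a, b per head. Softmax is computed with per-row max
  subtraction; ties are resolved by the softmax itself (no argmax anywhere).
- **Value vectors come from the sending side** of each phase (atoms during
  aggregation, masters during broadcast). The self-loop value is a separate
  linear map B_V^self of the node's own embedding.
- **The elementwise nonlinearity σ after aggregation** is applied after the
  weighted sum, and is tanh: masters persist across layers within a forward
  pass, and a bounded zero-centered nonlinearity keeps that recursion
  well-conditioned. (An alternative with fresh masters per layer is exposed
  as `masters_persist=False`.)
- **Positional encoding**: u = 1 − exp(−d/λ) with λ = 10 Å, then n_pe = 16
  Gaussians on [0, 1] with the same γ-from-spacing rule as the radial
  basis. The map is monotone, smooth, and saturating, so arbitrarily large
  systems produce valid encodings and no distance ever crosses a cutoff.
  The atom-to-center distance is regularized as √(d² + ε²), ε = 1e-6 Å,
  because |x − c| has a kink at the center and an atom can sit there.
- **Head mixing**: heads stay independent through the cycle (this is what
  makes per-head SVD interpretability meaningful); a final MLP
  (H·D_h → F → F) folds the concatenated head outputs back, residually.
  Its last layer is zero-initialized, so an untrained extended model equals
  the pure baseline exactly — the reduction property that anchors several
  tests.
- **Gates**: g_k = σ(ℓ_k) multiply master value contributions in the
  broadcast; the training loss adds penalty_weight · Σ g_k (default
  1e-3). Logits start at 2.0 (g ≈ 0.88) with a 0.5-σ random spread —
  degenerate masters have identical utility gradients, and without the
  spread nothing can break the tie between them. Gate logits carry a 100×
  learning-rate multiplier: they are O(1) allocation scalars, and
  Adam-normalized steps at the weight learning rate would move a logit by
  less than 0.1 over a typical run, freezing the allocation mechanism.

### Geometry

Neighbor lists use cell-list binning (O(N)) for open boundaries and the
minimum-image convention for periodic cells, with an explicit error when
the cutoff exceeds half the smallest perpendicular cell width. An O(N²)
brute-force scan (including 27 image cells) is kept in the test suite as
the oracle. Distances are computed in float64; the whole model runs in
float64 (at these desk scales the cost is negligible and every tolerance
in the test suite is comfortably met).

Master nodes sit at the unweighted centroid of the graph. For periodic
systems this is the wrapped-coordinate centroid — a documented convention;
the positional encoding is not periodic-image-aware, so periodic systems
exercise only the baseline pathway in anger.

## Differentiation

`rangeff.autodiff` is a small reverse-mode tape over numpy float64 arrays.
Vector-Jacobian products are themselves Tensor expressions, so
`grad(..., create_graph=True)` yields differentiable gradients: forces are
exact −∂E/∂x, and the force-matching loss is differentiated through them
(second order). Nonlinearity vjps recompute the primal from the input
rather than capturing the output node, keeping graphs acyclic so memory is
reclaimed by reference counting. Gather/scatter-add are the graph
primitives; segment softmax subtracts a per-segment maximum as a constant
shift.

## Training

Loss = energy_weight · MSE(ΔE/N_atoms) + force_weight · MSE(F) + gate
penalty, with defaults 0.05 / 0.95 — energies normalized per atom so mixed
system sizes contribute comparably. Optimizer: AdamW (lr 5e-4, weight decay
1e-6) with cosine decay to 1% over the run; 10% of frames are held out for
validation and the best-validation parameters are restored. Runs are
bitwise deterministic given the seed. An optional least-squares
initialization of the per-species reference energies from the composition
is available (`init_species_ref=True`) but off by default: on the dimer
study, joint learning of offsets and interactions reached better
extrapolating tails than pre-fitting the offset.

## Synthetic systems

The generators provide analytic LJ + Coulomb ground truth
(k_e = 332.0637 kcal·Å/(mol·e²); every generated frame passes a 1e-8
finite-difference force check):

- **Fragment dimers.** Rigid 5-atom square pyramids (edge 2 Å, apex 1.5 Å)
  in three classes: apolar (q = 0), polar (±0.3 e internal dipole, net 0),
  charged (uniform ±0.2 e, net ±1). LJ: ε = 0.05 kcal/mol, σ = 2.0 Å,
  Lorentz–Berthelot combination, all pairs (intra + inter). Frames place
  two uniformly rotated fragments at separation ~ U(4, 15) Å with 0.05 Å
  Gaussian jitter, re-evaluated analytically. The split is by distance:
  train ≤ 9 Å, test > 9 Å. For the charged pair the test-split interaction
  energy is the −k_e/r point-charge tail within ≲ 2% (multipole
  corrections) — beyond any message path of a 2-layer, 5 Å-cutoff network,
  which is the point.
- **Displaced-ion cluster.** A rock-salt-like cube of alternating ±1 e ions
  (spacing 2.82 Å, Born–Mayer repulsion A e^{−r/ρ}, A = 3·10⁴ kcal/mol,
  ρ = 0.317 Å) with one corner ion displaced outward along the body
  diagonal. For an even cube the remainder carries the opposite charge, so
  E(d) − E(∞) has a 1/d tail (fit r² ≥ 0.99 beyond 8 Å); the pristine
  lattice is the scan minimum.
- **Scaling gas.** Rejection-sampled LJ gas at fixed density
  (0.008 atoms/Å³, minimum spacing 0.8σ) for operation-count scaling only.

What these emulate — and what they do not: the dimers reproduce the
structure of charged/polar/apolar dimer extrapolation benchmarks with exact
references; they lack DFT-level many-body dispersion, polarization, and
conformational flexibility. Passing the study therefore demonstrates that
the architecture can recover beyond-cutoff physics from data, not that it
matches any particular quantum-chemistry dataset.

## Desk-scale study conditions

The training-based checks use: 500 charged-dimer frames (≈ 450 train after
the validation split, ≈ 315/185 train/test by distance), 140 epochs, batch
32, three seeds with majority voting, default architecture above. The
gate-allocation probe over-provisions K = 8 masters on a 200-frame dimer
task with a reduced-width host (F = 32, D_h = 4), batch 16, 90 epochs and
penalty_weight 0.2 — the stronger penalty is the probe's dose: at the
training default (1e-3) the marginal-utility gradient of even redundant
masters exceeds the penalty on this small task and no gate moves. MD
stability runs 10 000 BAOAB steps (1 fs, 300 K, friction 0.001 fs⁻¹) on
the trained model, three replicas advanced as one batch.

## Molecular dynamics

BAOAB splitting of Langevin dynamics; with zero friction it reduces exactly
to velocity Verlet (energy drift ≤ 1e-4 relative over 10⁴ steps on a
harmonic oracle), and the O-step noise obeys fluctuation–dissipation
(equipartition to 300 K within 5% on the same oracle). Masses come from an
embedded standard-atomic-weight table (Z ≤ 86). Units: Å, fs, amu,
kcal/mol, with 1 (kcal/mol/Å)/amu = 4.184·10⁻⁴ Å/fs². A run is declared
stable if all coordinates stay finite and no pair distance drops below
0.5 Å; on violation the trajectory is truncated and flagged, never
silently discarded.

## Interpretability

Attention matrices (aggregation K×N, broadcast N×(K+1) with the self-loop
as last column) are recorded per layer and head — recording is purely
observational (bit-identical energies). For one (layer, head, master) the
frames × N stack is column-centered (raw mode available) and decomposed by
thin SVD; the principal right-singular vector is sign-fixed (largest-
magnitude entry positive) and the spectrum normalized to sum 1. Which
matrix to decompose was an open choice; the per-(layer, head, master)
frames × N convention is this package's documented one.

## Numerical notes and limitations

- Attention-score evaluations are counted exactly (N·K·H per phase per
  layer); wall time is reported but never asserted.
- The op-count linear fit snaps residuals to integers (counts are exact).
- Checkpoints are npz archives of parameter arrays plus a JSON config.
- Known limitations: no periodic positional encoding; no master–master
  attention; no learned master positions; single-device training only;
  float64-only (no mixed precision); the gate probe demonstrates the
  allocation mechanism, not a universal sparsification guarantee.
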