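# rangeff

Message-passing interatomic potentials are local: each atom sees only
neighbors within a cutoff radius (typically ~5 Å), and stacking T interaction
layers extends the field of view to at most T·r_c. Electrostatics and
dispersion act far beyond that, so local models *cannot* predict, e.g., how
the energy of a pair of charged molecules changes with their separation once
they drift out of the cutoff — they go exactly flat. `rangeff` is a
desk-scale laboratory for the virtual-node attention remedy: a handful of
global "master" nodes that aggregate information from every atom via
attention and broadcast it back, restoring long-range physics at a cost
linear in the number of atoms.

The package is aimed at researchers studying long-range corrections for
machine-learned force fields (MLFFs) who want a small, fully inspectable
implementation with analytic ground truth instead of DFT datasets.

## The model

A SchNet-style invariant baseline updates per-atom embeddings
**h**ᵢ⁽ᵗ⁺¹⁾ = **h**ᵢ⁽ᵗ⁾ + MLP(**m**ᵢ⁽ᵗ⁾) with continuous-filter messages

```
mᵢ = Σ_{j∈N(i)}  W_filt(rbf(d_ij)) ⊙ (W₁ h_j) · f_cut(d_ij)
```

After every interaction layer, K virtual master nodes placed at the
geometric center run an aggregation–broadcast cycle with H independent
additive-attention heads (GATv2-style scoring):

```
aggregation:  s_{k,i} = aᵀ LeakyReLU(A_Q M_k + A_K h_i + A_E p_i)
              α = softmax_i(s),   M'_k = σ(Σ_i α_{k,i} A_V h_i)
broadcast:    t_{i,k} = bᵀ LeakyReLU(B_Q h_i + B_K M'_k + B_E p_i)
              β = softmax over {K masters} ∪ {self-loop}
              o_i = β_self B_V^self h_i + Σ_k g_k β_{i,k} B_V M'_k
mixing:       h_i ← h_i + MLP(concat_heads o_i)
```

**p**ᵢ is an SE(3)-invariant positional encoding: the atom-to-center
distance is mapped to u = 1 − exp(−d/λ) ∈ [0,1) and expanded in Gaussian
radial basis functions — smooth everywhere and defined at any distance, so
energies and forces stay continuous (no cutoff anywhere in the cycle). The
sigmoid gates g_k carry an L1 penalty that lets training deactivate masters
a task does not need. Energy is an atom-wise readout sum; forces are exact
gradients −∂E/∂x via the package's reverse-mode autodiff core (which also
supplies the second-order gradients force-matching training needs).

Everything runs in plain numpy/scipy; structures are extended XYZ;
units are Å, kcal/mol, kcal/mol/Å, fs.

## Worked example

`examples/02_train_and_extrapolate.py` trains a model on rigid charged
(±1 e) 5-atom fragment dimers at separations 4–9 Å and evaluates on
9–15 Å — beyond the 5 Å cutoff, so the task is pure extrapolation:

```
training on 243 frames (≤ 9 Å), testing on 257 (> 9 Å)
  virtual-node attention: test MAE   4.35 kcal/mol (0.268 kcal/mol/Å on forces), correlation with Coulomb tail r = +0.955
          local baseline: test MAE  21.09 kcal/mol (0.264 kcal/mol/Å on forces), correlation with Coulomb tail r = +0.053
```

The baseline predicts a constant energy beyond its cutoff (its correlation
with the −k_e/r Coulomb tail is noise around zero), while the
attention-extended model tracks a tail it never saw during training: a
5× lower extrapolation error. The same study over three seeds backs the
acceptance suite in `tests/test_acceptance.py`; see `docs/methods.md` for
the conditions.

Other examples: dataset generation (`01`), Langevin MD with stability
observables (`03`), SVD attention interpretability (`04`), and the
linear-scaling benchmark (`05`). A thin CLI covers the same surface:

```
rangeff generate --preset dimer-cc --n 500 --seed 1 --out dimers.xyz
rangeff train --config train.yaml
rangeff simulate --checkpoint model.npz --in start.xyz --steps 10000 --out traj.xyz
rangeff analyze-attention --checkpoint model.npz --traj traj.xyz --out attn.h5
```

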