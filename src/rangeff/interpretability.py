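"""SVD analysis of attention-weight distributions.

Collecting the aggregation (K×N) and broadcast (N×(K+1)) attention matrices
over many frames and decomposing the per-(layer, head, master) frames × N
stack reveals each head's dominant "clustering strategy": the right singular
vector of the largest singular value assigns a weight to every graph node,
which can be exported as a per-atom column for molecular viewers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graph_core import AtomicConfiguration
from .model_training import EnergyModel, prepare_batch
from .range_layer import AttentionRecord


@dataclass
class AttentionStore:
    """agg: (frames, layers, H, K, N); bro: (frames, layers, H, N, K+1)."""

    agg: np.ndarray
    bro: np.ndarray


@dataclass
class AttentionMatrixStack:
    """A frames × N matrix of attention rows for one (layer, head, master)."""

    W: np.ndarray
    layer: int = 0
    head: int = 0
    master: int = 0
    phase: str = "agg"


def collect_attention(model: EnergyModel, frames) -> AttentionStore:
    """Run recorded forward passes over frames (all with the same atom count)."""
    if not model.config.range_enabled:
        raise ValueError("attention recording requires a RANGE-enabled model")
    from . import autodiff as ad

    aggs, bros = [], []
    for cfg in frames:
        batch = prepare_batch([cfg], model.config.baseline.cutoff,
                              model.config.range_hp.n_masters)
        rec = AttentionRecord()
        with ad.no_grad():
            model.forward(batch, record=rec)
        aggs.append(np.stack(rec.agg))   # (layers, H, K, N)
        bros.append(np.stack(rec.bro))   # (layers, H, N, K+1)
    return AttentionStore(agg=np.stack(aggs), bro=np.stack(bros))


def build_stack(store: AttentionStore, layer: int, head: int, master: int,
                phase: str = "agg") -> AttentionMatrixStack:
    if phase == "agg":
        W = store.agg[:, layer, head, master, :]
    elif phase == "bro":
        W = store.bro[:, layer, head, :, master]
    else:
        raise ValueError("phase must be 'agg' or 'bro'")
    return AttentionMatrixStack(W=W.copy(), layer=layer, head=head,
                                master=master, phase=phase)


def svd_principal_component(stack: AttentionMatrixStack, center: bool = True):
    """Leading right-singular vector and the normalized singular spectrum.

    The stack is column-centered by default (raw mode via ``center=False``).
    The sign is fixed so the vector's largest-magnitude entry is positive;
    the spectrum is normalized to sum 1.
    """
    W = np.asarray(stack.W, dtype=np.float64)
    if W.shape[0] < 2:
        raise ValueError("need at least 2 frames for an SVD analysis")
    if center:
        W = W - W.mean(axis=0, keepdims=True)
    _, s, vt = np.linalg.svd(W, full_matrices=False)
    v1 = vt[0]
    if v1[np.argmax(np.abs(v1))] < 0:
        v1 = -v1
    total = s.sum()
    spectrum = s / total if total > 0 else s
    return v1, spectrum


def head_dominance(spectrum: np.ndarray) -> float:
    """Share of the largest singular value, σ₁ / Σσ."""
    spectrum = np.asarray(spectrum, dtype=np.float64)
    total = spectrum.sum()
    return float(spectrum[0] / total) if total > 0 else 0.0


def dominance_table(store: AttentionStore, phase: str = "agg", master: int = 0,
                    center: bool = True) -> np.ndarray:
    """(layers, heads) dominance ratios for one master."""
    n_layers, n_heads = store.agg.shape[1], store.agg.shape[2]
    out = np.zeros((n_layers, n_heads))
    for l in range(n_layers):
        for h in range(n_heads):
            _, spec = svd_principal_component(
                build_stack(store, l, h, master, phase), center=center
            )
            out[l, h] = head_dominance(spec)
    return out


def export_node_coloring(component: np.ndarray, config: AtomicConfiguration,
                         path, column: str = "attn_pc1") -> None:
    """Write the frame with the component as an extra per-atom real column."""
    from .extxyz import write_extxyz

    component = np.asarray(component, dtype=np.float64).reshape(-1)
    if len(component) != config.n_atoms:
        raise ValueError("component length does not match atom count")
    write_extxyz(path, [config], extra_columns={column: [component]})


def read_node_coloring(path, column: str = "attn_pc1") -> np.ndarray:
    from .extxyz import read_extxyz

    cfg = read_extxyz(path)[0]
    key = f"column:{column}"
    if key not in cfg.tags:
        raise ValueError(f"no column {column!r} in {path}")
    return np.array([float(v) for v in cfg.tags[key].split()])


def save_attention_h5(store: AttentionStore, path) -> None:
    """HDF5 layout: agg/{layer}/{head} → (frames, K, N); bro/... → (frames, N, K+1)."""
    import h5py

    with h5py.File(path, "w") as f:
        n_layers, n_heads = store.agg.shape[1], store.agg.shape[2]
        for phase, arr in (("agg", store.agg), ("bro", store.bro)):
            for l in range(n_layers):
                for h in range(n_heads):
                    f.create_dataset(f"{phase}/{l}/{h}", data=arr[:, l, h])
        f.create_dataset("frame_index", data=np.arange(store.agg.shape[0]))
        f.create_dataset("atom_index", data=np.arange(store.agg.shape[-1]))


def load_attention_h5(path) -> AttentionStore:
    import h5py

    with h5py.File(path, "r") as f:
        layers = sorted(int(k) for k in f["agg"].keys())
        heads = sorted(int(k) for k in f["agg/0"].keys())
        agg = np.stack(
            [np.stack([f[f"agg/{l}/{h}"][()] for h in heads], axis=1) for l in layers],
            axis=1,
        )
        bro = np.stack(
            [np.stack([f[f"bro/{l}/{h}"][()] for h in heads], axis=1) for l in layers],
            axis=1,
        )
    return AttentionStore(agg=agg, bro=bro)
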