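"""Gradient-weighted regression activation mapping (Grad-RAM).

For a trained regressor, the localization map over the last convolutional
layer of a branch is

    L = ReLU( sum_k alpha_k * A^k )

where A^k is the k-th feature map and alpha_k pools the gradient of the
prediction y-hat w.r.t. A^k over positions: the mean for the GAP variant,
the max for the GMP variant.  In the guided variants the gradient is first
masked elementwise to g * 1[A > 0] * 1[g > 0], keeping only positions where
both the activation and the gradient are positive.  Because convolutions
preserve length, map positions align 1:1 with input residues/characters;
weights are left un-normalized so that rank-based relevance statistics act
on raw positive values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["FeatureMapStack", "LocalizationMap", "VARIANTS",
           "feature_gradients", "gradram_map", "project_to_input",
           "maps_for_batch"]

VARIANTS = ("GMP-G", "GMP-NG", "GAP-G", "GAP-NG")


@dataclass(frozen=True)
class FeatureMapStack:
    """Last-conv activations and d(y-hat)/dA for one input, shape (u, k)."""

    activations: np.ndarray
    gradients: np.ndarray

    def __post_init__(self) -> None:
        if self.activations.shape != self.gradients.shape:
            raise ValueError("activation/gradient shape mismatch")
        if self.activations.size == 0:
            raise ValueError("empty feature map stack")
        if not np.all(np.isfinite(self.gradients)):
            raise ValueError("non-finite gradients")


@dataclass(frozen=True)
class LocalizationMap:
    """Nonnegative per-position relevance weights for one prediction."""

    values: np.ndarray
    branch: str  # "protein" | "smiles"
    variant: str  # one of VARIANTS


def feature_gradients(net, xp: np.ndarray, xs: np.ndarray, branch: str) -> FeatureMapStack:
    """Activations and exact backpropagated gradients for a single pair.

    ``xp``/``xs`` are single one-hot inputs of shape (L, dict) or batches of
    one.  For batch processing use :func:`maps_for_batch`.
    """
    if xp.ndim == 2:
        xp = xp[None]
    if xs.ndim == 2:
        xs = xs[None]
    acts, grads = net.feature_map_gradients(xp, xs, branch)
    return FeatureMapStack(activations=acts[0], gradients=grads[0])


def _pooled_weights(grad: np.ndarray, act: np.ndarray, pooling: str, guided: bool):
    if guided:
        grad = grad * (act > 0) * (grad > 0)
    if pooling == "GAP":
        return grad.mean(axis=-2)  # mean over positions -> (k,)
    if pooling == "GMP":
        return grad.max(axis=-2)
    raise ValueError(f"unknown pooling {pooling!r}")


def gradram_map(stack: FeatureMapStack, pooling: str, guided: bool,
                branch: str = "protein") -> LocalizationMap:
    """Localization map from one feature-map stack.

    alpha_k = mean_u g[u,k] (GAP) or max_u g[u,k] (GMP), with g the guided
    or raw gradient; map = ReLU(sum_k alpha_k A^k) per position u.
    """
    alpha = _pooled_weights(stack.gradients, stack.activations, pooling, guided)
    values = np.maximum(stack.activations @ alpha, 0.0)
    variant = f"{pooling}-{'G' if guided else 'NG'}"
    return LocalizationMap(values=values, branch=branch, variant=variant)


def project_to_input(loc: LocalizationMap, mask: np.ndarray) -> LocalizationMap:
    """Zero out weights on padded positions; values elsewhere unchanged."""
    if loc.values.shape[0] != mask.shape[0]:
        raise ValueError(
            f"map length {loc.values.shape[0]} != mask length {mask.shape[0]}"
        )
    return LocalizationMap(values=loc.values * (mask > 0), branch=loc.branch,
                           variant=loc.variant)


def maps_for_batch(net, xp: np.ndarray, xs: np.ndarray, branch: str,
                   variant: str, masks: np.ndarray | None = None) -> list[LocalizationMap]:
    """Localization maps of one variant for every pair in a batch."""
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    pooling, g = variant.split("-")
    guided = g == "G"
    acts, grads = net.feature_map_gradients(xp, xs, branch)
    out = []
    for i in range(acts.shape[0]):
        stack = FeatureMapStack(activations=acts[i], gradients=grads[i])
        loc = gradram_map(stack, pooling, guided, branch=branch)
        if masks is not None:
            loc = project_to_input(loc, masks[i])
        out.append(loc)
    return out


def write_map_tsv(path, loc: LocalizationMap, sequence: str) -> None:
    """TSV per pair: 1-based position, residue/character, weight, variant, branch."""
    with open(path, "w") as fh:
        fh.write("position\tsymbol\tweight\tvariant\tbranch\n")
        for i, w in enumerate(loc.values):
            sym = sequence[i] if i < len(sequence) else "-"
            fh.write(f"{i + 1}\t{sym}\t{float(w)!r}\t{loc.variant}\t{loc.branch}\n")


def read_map_tsv(path) -> tuple[LocalizationMap, str]:
    """Inverse of :func:`write_map_tsv`; weights round-trip bit-exactly."""
    values, symbols, variant, branch = [], [], "GMP-G", "protein"
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("position\t"):
            raise ValueError(f"{path}: not a localization-map TSV")
        for line in fh:
            pos, sym, w, variant, branch = line.rstrip("\n").split("\t")
            values.append(float(w))
            symbols.append(sym)
    seq = "".join(s for s in symbols if s != "-")
    return LocalizationMap(values=np.array(values), branch=branch, variant=variant), seq


def plot_map(loc: LocalizationMap, sequence: str, sites=None, ax=None):
    """Vertical-line importance plot of a localization map (optional matplotlib)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 2.5))
    pos = np.arange(1, len(loc.values) + 1)
    ax.vlines(pos, 0, loc.values, color="0.3", lw=0.8)
    if sites:
        ax.scatter(list(sites), [0] * len(sites), color="crimson", zorder=3, s=12)
    ax.set_xlabel("position")
    ax.set_ylabel("weight")
    ax.set_title(f"{loc.branch} {loc.variant}")
    return ax
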