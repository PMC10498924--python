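"""Gradient-variance (VarGrad) explainability and heatmap stratification.

A saliency map is the gradient of the model's class-1 probability with
respect to every input voxel/channel. VarGrad perturbs the input with
Gaussian noise ``n_repeats`` times (default 20), recomputes the saliency
map each time, and takes the per-voxel variance, normalized to [0, 1] by
its global maximum. The heatmap can then be stratified by SUV bins, HU
bins relative to the CT window center, and tumor/node/other location.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import Tensor

DEFAULT_SUV_EDGES = (0.0, 2.0, 10.0, np.inf)
DEFAULT_HU_EDGES_RELATIVE = (-np.inf, -50.0, 0.0, 50.0, np.inf)


@dataclass
class VarGradMap:
    heatmap: np.ndarray            # (C, D, H, W), nonnegative, max 1 unless all-zero
    n_repeats: int
    noise_sd: np.ndarray           # per channel
    display_threshold: float = 0.25

    @property
    def spatial(self) -> np.ndarray:
        """Across-channel maximum; one value per voxel (for overlays)."""
        return self.heatmap.max(axis=0)


@dataclass
class StratifiedImportance:
    suv: dict[str, float] = field(default_factory=dict)
    hu: dict[str, float] = field(default_factory=dict)
    region: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"suv": self.suv, "hu": self.hu, "region": self.region}


def saliency(model, input_volume: np.ndarray) -> np.ndarray:
    """Gradient of the class-1 probability w.r.t. each input voxel/channel.

    The model must expose ``forward_tensor`` (the differentiable members of
    the family do); anything else — e.g. a random forest — is rejected by
    class name.
    """
    if not hasattr(model, "forward_tensor"):
        raise TypeError(
            f"{type(model).__name__} is not differentiable; saliency requires "
            "a model exposing forward_tensor")
    x = np.asarray(input_volume, dtype=np.float64)
    squeeze = x.ndim == 4
    if squeeze:
        x = x[None]
    tensor = Tensor(x, requires_grad=True)
    prob = model.forward_tensor(tensor)
    prob.sum().backward()
    grad = tensor.grad
    return grad[0] if squeeze else grad


def vargrad(model, input_volume: np.ndarray, n_repeats: int = 20,
            noise_sd=None, seed: int = 0,
            display_threshold: float = 0.25) -> VarGradMap:
    """Per-voxel variance of `n_repeats` noisy-input saliency maps.

    Default noise is Gaussian with sd = 0.05 x the dynamic range of each
    input channel (0.05 for constant channels). The map is normalized by
    its global maximum; an affine model yields an identically zero map.
    """
    if n_repeats < 2:
        raise ValueError("n_repeats must be >= 2")
    x = np.asarray(input_volume, dtype=np.float64)
    if x.ndim != 4:
        raise ValueError("input volume must be (C, D, H, W)")
    n_channels = x.shape[0]
    if noise_sd is None:
        rng_per_ch = x.reshape(n_channels, -1).max(axis=1) - \
            x.reshape(n_channels, -1).min(axis=1)
        noise_sd = 0.05 * np.where(rng_per_ch > 0, rng_per_ch, 1.0)
    else:
        noise_sd = np.broadcast_to(np.asarray(noise_sd, dtype=np.float64),
                                   (n_channels,)).copy()
        if np.any(noise_sd <= 0):
            raise ValueError("noise_sd must be positive")
    rng = np.random.default_rng(seed)
    grads = np.empty((n_repeats,) + x.shape)
    for r in range(n_repeats):
        noisy = x + rng.standard_normal(x.shape) * noise_sd[:, None, None, None]
        grads[r] = saliency(model, noisy)
    heatmap = grads.var(axis=0)
    # kill pure floating-point jitter (identical gradients, e.g. affine
    # models, must give an exactly zero map)
    scale = (grads ** 2).mean(axis=0)
    heatmap[heatmap <= 1e-18 * np.maximum(scale, 1e-300)] = 0.0
    peak = heatmap.max()
    if peak > 0:
        heatmap = heatmap / peak
    return VarGradMap(heatmap, n_repeats, noise_sd, display_threshold)


def _bin_labels(edges) -> list[str]:
    labels = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        labels.append(f"[{lo:g}, {hi:g})")
    return labels


def _stratify(values: np.ndarray, heat: np.ndarray, edges) -> dict[str, float]:
    out = {}
    for label, lo, hi in zip(_bin_labels(edges), edges[:-1], edges[1:]):
        sel = (values >= lo) & (values < hi)
        if sel.any():
            out[label] = float(heat[sel].mean())
    return out


def stratify_importance(vargrad_map: VarGradMap, pet: np.ndarray, ct: np.ndarray,
                        gtvp: np.ndarray, gtvn: np.ndarray,
                        suv_edges=DEFAULT_SUV_EDGES,
                        hu_edges_relative=DEFAULT_HU_EDGES_RELATIVE,
                        hu_center: float = 70.0) -> StratifiedImportance:
    """Mean heatmap value per SUV bin, HU bin (relative to the window
    center) and tumor/node/other region (tumor wins where masks overlap).

    Empty strata are omitted from the result rather than reported as 0.
    """
    heat = vargrad_map.spatial
    pet = np.asarray(pet, dtype=np.float64)
    ct = np.asarray(ct, dtype=np.float64)
    if heat.shape != pet.shape or heat.shape != ct.shape:
        raise ValueError("heatmap and volumes must share shape")
    gtvp_b = np.asarray(gtvp).astype(bool)
    gtvn_b = np.asarray(gtvn).astype(bool) & ~gtvp_b

    result = StratifiedImportance()
    result.suv = _stratify(pet, heat, suv_edges)
    result.hu = _stratify(ct - hu_center, heat, hu_edges_relative)
    for name, mask in (("tumor", gtvp_b), ("node", gtvn_b),
                       ("other", ~gtvp_b & ~gtvn_b)):
        if mask.any():
            result.region[name] = float(heat[mask].mean())
    return result


def render_heatmap_overlay(vargrad_map: VarGradMap, pet: np.ndarray,
                           ct: np.ndarray, gtvp: np.ndarray,
                           gtvn: np.ndarray | None = None,
                           display_threshold: float | None = None,
                           slice_index: int | None = None):
    """Fused PET/CT axial slice with the heatmap shown above threshold.

    Returns a matplotlib Figure; mask contours are drawn on top.
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    from .imaging import WindowSpec, window_ct

    if display_threshold is None:
        display_threshold = vargrad_map.display_threshold
    heat = vargrad_map.spatial
    gtvp_b = np.asarray(gtvp).astype(bool)
    if slice_index is None:
        slice_index = int(round(np.argwhere(gtvp_b)[:, 0].mean())) if gtvp_b.any() \
            else heat.shape[0] // 2

    ct_disp = window_ct(ct, WindowSpec())[slice_index]
    pet_disp = np.asarray(pet, dtype=np.float64)[slice_index]
    pet_disp = pet_disp / max(pet_disp.max(), 1e-9)
    fused = 0.5 * ct_disp + 0.5 * pet_disp
    heat_slice = np.ma.masked_less_equal(heat[slice_index], display_threshold)

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.imshow(fused, cmap="gray", vmin=0, vmax=1)
    ax.imshow(heat_slice, cmap="hot", vmin=0, vmax=1, alpha=0.6)
    ax.contour(gtvp_b[slice_index], levels=[0.5], colors="cyan", linewidths=1)
    if gtvn is not None and np.asarray(gtvn).astype(bool)[slice_index].any():
        ax.contour(np.asarray(gtvn).astype(bool)[slice_index], levels=[0.5],
                   colors="lime", linewidths=1)
    ax.set_axis_off()
    return fig
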