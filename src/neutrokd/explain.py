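"""Grad-CAM++ saliency maps with per-image uncertainty annotations.

The class score used for gradients is the pre-softmax logit of the target
class.  Grad-CAM++ pixel weights are computed from the first, second and
third powers of the class-score gradient with respect to the target layer's
activation maps:

    alpha_ij^k = g_ij^2 / (2 g_ij^2 + sum_ab A_ab^k g_ab^3)
    w_k        = sum_ij alpha_ij^k relu(g_ij)
    map        = relu(sum_k w_k A^k)

followed by bilinear upsampling to the input size and min-max normalization
(an all-zero map stays all-zero).  Each explained image is annotated with the
student's confidence (max probability), normalized entropy, and margin-based
indeterminacy — the same ambiguity measure the distillation weighting uses,
here computed from the explained student's own distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import matplotlib
import numpy as np
from skimage.transform import resize

from .models import Network, target_layer_for_cam
from .nkd_core import DistillationConfig, neutrosophic_triplet, soften

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

__all__ = ["ExplanationRecord", "grad_cam_pp", "explain_batch", "overlay_heatmap"]


@dataclass
class ExplanationRecord:
    heatmap: np.ndarray
    predicted_class: int
    confidence: float
    entropy: float
    indeterminacy: float
    overlay: np.ndarray


def grad_cam_pp(
    network: Network,
    image: np.ndarray,
    target_class: int | None = None,
    target_layer: int | None = None,
) -> np.ndarray:
    """Grad-CAM++ heatmap in [0, 1] with the spatial shape of the input."""
    x = np.asarray(image, dtype=np.float32)
    if x.ndim == 3:
        x = x[None]
    if x.ndim != 4 or x.shape[0] != 1:
        raise ValueError("grad_cam_pp explains a single C x H x W image")
    t = target_layer_for_cam(network) if target_layer is None else target_layer
    logits = network.forward(x, train=False, record=True)
    activations = network._outs[t]
    if activations.ndim != 4:
        raise ValueError(f"layer {t} has no spatial extent; pick a convolutional layer")
    cls = int(logits[0].argmax()) if target_class is None else int(target_class)

    donehot = np.zeros_like(logits)
    donehot[0, cls] = 1.0
    grad = network.backward(donehot, until=t + 1)

    a = activations[0].astype(np.float64)  # (K, h, w)
    g = grad[0].astype(np.float64)
    g2 = g * g
    g3 = g2 * g
    denom = 2.0 * g2 + (a * g3).sum(axis=(1, 2), keepdims=True)
    alpha = np.where(np.abs(denom) > 1e-12, g2 / np.where(denom == 0, 1.0, denom), 0.0)
    weights = (alpha * np.maximum(g, 0.0)).sum(axis=(1, 2))
    cam = np.maximum((weights[:, None, None] * a).sum(axis=0), 0.0)

    cam = resize(cam, x.shape[2:], order=1, anti_aliasing=False, preserve_range=True)
    peak = cam.max()
    return cam / peak if peak > 0 else cam


def overlay_heatmap(
    rgb_image: np.ndarray, heatmap: np.ndarray, alpha: float = 0.4, cmap: str = "jet"
) -> np.ndarray:
    """Alpha-blend a colormapped heatmap over an RGB uint8 image."""
    base = np.asarray(rgb_image, dtype=np.float64) / 255.0
    if heatmap.shape != base.shape[:2]:
        heatmap = resize(heatmap, base.shape[:2], order=1, preserve_range=True)
    colored = matplotlib.colormaps[cmap](np.clip(heatmap, 0, 1))[..., :3]
    blended = (1 - alpha) * base + alpha * colored
    return np.clip(np.rint(blended * 255.0), 0, 255).astype(np.uint8)


def explain_batch(
    network: Network,
    images: np.ndarray,
    labels: np.ndarray,
    distill_config: DistillationConfig | None = None,
    originals: list[np.ndarray] | None = None,
    class_names: list[str] | None = None,
    target_layer: int | None = None,
):
    """Explain a batch of standardized images.

    Returns ``(records, figure)``: one :class:`ExplanationRecord` per image
    and a gallery figure grouped by class with annotation text.
    """
    images = np.asarray(images, dtype=np.float32)
    labels = np.asarray(labels)
    n = images.shape[0]
    logits = network.logits(images)
    records = []
    for i in range(n):
        probs = soften(logits[i], temperature=1.0)
        trip = neutrosophic_triplet(probs, mode="margin")
        nz = probs[probs > 0]
        entropy = float(-(nz * np.log(nz)).sum() / np.log(probs.shape[0]))
        heatmap = grad_cam_pp(network, images[i], target_layer=target_layer)
        if originals is not None:
            base = originals[i]
        else:  # reconstruct a displayable base from the standardized tensor
            t = images[i].transpose(1, 2, 0)
            t = (t - t.min()) / (t.max() - t.min() + 1e-9)
            base = np.rint(t * 255.0).astype(np.uint8)
        records.append(
            ExplanationRecord(
                heatmap=heatmap,
                predicted_class=int(probs.argmax()),
                confidence=float(probs.max()),
                entropy=entropy,
                indeterminacy=trip.indeterminacy,
                overlay=overlay_heatmap(base, heatmap),
            )
        )

    order = np.argsort(labels, kind="stable")
    ncols = min(5, max(1, n))
    nrows = -(-n // ncols)
    fig, axes = plt.subplots(nrows, ncols, figsize=(3 * ncols, 3.2 * nrows), squeeze=False)
    for ax in axes.ravel():
        ax.axis("off")
    for slot, i in enumerate(order):
        ax = axes[slot // ncols][slot % ncols]
        rec = records[i]
        ax.imshow(rec.overlay)
        true_name = (
            class_names[labels[i]] if class_names is not None else f"class {labels[i]}"
        )
        ax.set_title(
            f"{true_name}\npred={rec.predicted_class} conf={rec.confidence:.2f}\n"
            f"H={rec.entropy:.2f} I={rec.indeterminacy:.2f}",
            fontsize=7,
        )
    fig.tight_layout()
    return records, fig
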