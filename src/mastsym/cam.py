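"""Class activation mapping.

The per-side category feature maps and the symmetry path's grade maps are
spatial class-evidence grids (one channel per category or grade).  A CAM is
one such channel, rectified (ReLU) and bilinearly upsampled to the input
resolution; no gradients are involved.  The standard visual panel for one
study has 12 subpanels: each side's original image with its three category
CAMs, and the inter-ear difference image with the three symmetry-grade
CAMs, each annotated with the model's probability.
"""

from __future__ import annotations

import numpy as np
from skimage.transform import resize as _sk_resize

__all__ = ["cam_category", "cam_symmetry", "render_cam_panel"]


def _chw(fm: np.ndarray) -> np.ndarray:
    fm = np.asarray(fm, dtype=float)
    if fm.ndim != 3:
        raise ValueError("feature map must be 3-D")
    if fm.shape[0] != 3 and fm.shape[2] == 3:
        fm = fm.transpose(2, 0, 1)
    if fm.shape[0] != 3:
        raise ValueError(f"expected 3 class channels, got shape {fm.shape}")
    return fm


def _upsample_channel(channel: np.ndarray, out_shape) -> np.ndarray:
    rectified = np.maximum(channel, 0.0)
    return _sk_resize(rectified, out_shape, order=1, anti_aliasing=False,
                      preserve_range=True)


def cam_category(fm, class_index: int, out_shape=(384, 256)) -> np.ndarray:
    """Activation map of one mastoiditis category from a per-side feature
    map: the class channel, ReLU-rectified and upsampled to input size."""
    fm = _chw(fm)
    if class_index not in (0, 1, 2):
        raise ValueError("class_index must be 0 (normal), 1 (mild) or 2 (severe)")
    return _upsample_channel(fm[class_index], out_shape)


def cam_symmetry(grade_fm, grade_index: int, out_shape=(384, 256)) -> np.ndarray:
    """Activation map of one symmetry grade from the symmetry path's
    pre-pooling grade map (the absolute-difference map after the grade
    channel mapping, or the raw difference map for the direct head)."""
    fm = _chw(grade_fm)
    if grade_index not in (0, 1, 2):
        raise ValueError("grade_index must be 0, 1 or 2")
    return _upsample_channel(fm[grade_index], out_shape)


def render_cam_panel(pair, net, path=None):
    """Render the 12-subpanel CAM figure for one preprocessed study.

    Rows: right ear image + its three category CAMs; left ear likewise;
    inter-ear difference image + the three symmetry-grade CAMs.  Strongly
    reactive regions are red, intermediate white, unreacted blue (diverging
    map with the midpoint at half the panel maximum).  Returns the figure;
    saves to ``path`` when given.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import TwoSlopeNorm

    outs = net.predict_batch(pair.right_image, pair.left_image)
    shape = pair.right_image.shape
    p_r = outs.right_probs[0]
    p_l = outs.left_probs[0]
    p_s = outs.symmetry_probs[0]
    cat_names = ("normal", "mild", "severe")

    fig, axes = plt.subplots(3, 4, figsize=(10, 11))
    for ax in axes.ravel():
        ax.set_axis_off()

    def _draw(ax, cam, title):
        vmax = float(cam.max())
        if vmax <= 0:
            vmax = 1.0
        ax.imshow(cam, cmap="bwr", norm=TwoSlopeNorm(vmin=0.0, vcenter=vmax / 2, vmax=vmax))
        ax.set_title(title, fontsize=8)

    axes[0, 0].imshow(pair.right_image, cmap="gray")
    axes[0, 0].set_title("right ear", fontsize=8)
    axes[1, 0].imshow(pair.left_image, cmap="gray")
    axes[1, 0].set_title("left ear (oriented)", fontsize=8)
    axes[2, 0].imshow(np.abs(pair.right_image - pair.left_image), cmap="gray")
    axes[2, 0].set_title("|right - left|", fontsize=8)

    for k in range(3):
        _draw(axes[0, k + 1], cam_category(outs.fm_right[0], k, shape),
              f"R {cat_names[k]}  p={p_r[k]:.3f}")
        _draw(axes[1, k + 1], cam_category(outs.fm_left[0], k, shape),
              f"L {cat_names[k]}  p={p_l[k]:.3f}")
        _draw(axes[2, k + 1], cam_symmetry(outs.grade_fm[0], k, shape),
              f"grade {k}  p={p_s[k]:.3f}")

    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
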