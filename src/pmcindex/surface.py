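"""PMC-surface construction and 3-D rendering.

The first nine primary scores of a policy are arranged column-major into a
3x3 matrix,

    [[X1, X4, X7],
     [X2, X5, X8],
     [X3, X6, X9]],

and rendered as a 3-D surface; depressions localise the dimensions where the
policy text is weak.  X10 (policy disclosure) is excluded so the matrix is
square and balanced — on the default schema it scores 1 for every openly
published policy anyway.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .scoring import PolicyScore

__all__ = ["SurfaceMatrix", "surface_matrix", "render_surface"]

# column-major layout of X1..X9; row r, col c holds X(3*c + r + 1)
_LAYOUT = [["X1", "X4", "X7"],
           ["X2", "X5", "X8"],
           ["X3", "X6", "X9"]]


@dataclass(frozen=True)
class SurfaceMatrix:
    """3x3 arrangement of the first nine primary scores of one policy."""

    policy_id: str
    cells: np.ndarray  # shape (3, 3), values in [0, 1]
    grade: str = ""

    def __post_init__(self) -> None:
        c = np.asarray(self.cells, dtype=float)
        if c.shape != (3, 3):
            raise ValueError(f"surface matrix must be 3x3, got {c.shape}")
        object.__setattr__(self, "cells", c)


def surface_matrix(score: PolicyScore) -> SurfaceMatrix:
    """Arrange a policy's X1..X9 scores into the 3x3 surface layout.

    Defined only for the 10-primary layout (X1..X10); X10 is dropped.
    """
    needed = {f"X{i}" for i in range(1, 11)}
    if not needed <= set(score.primary_ids):
        raise ValueError(
            "the PMC surface is defined for the 10-primary layout X1..X10; "
            f"got primaries {score.primary_ids}")
    cells = np.array([[score.score_of(pid) for pid in row] for row in _LAYOUT])
    return SurfaceMatrix(score.policy_id, cells, score.grade)


def _bilinear_refine(cells: np.ndarray, factor: int) -> tuple[np.ndarray, ...]:
    """Bilinear interpolation of the 3x3 grid onto a finer mesh over [1, 3]^2."""
    base = np.arange(1.0, 4.0)
    fine = np.linspace(1.0, 3.0, 2 * factor + 1)
    # separable 1-D linear interpolation, rows then columns
    rows = np.array([np.interp(fine, base, cells[:, c]) for c in range(3)]).T
    grid = np.array([np.interp(fine, base, rows[r, :]) for r in range(len(fine))])
    xx, yy = np.meshgrid(fine, fine)
    return xx, yy, grid


def render_surface(
    matrix: SurfaceMatrix,
    out: str | Path,
    *,
    interpolate: bool = True,
    refine: int = 12,
    annotate_min: bool = True,
    cmap: str = "viridis",
    elev: float = 28.0,
    azim: float = -60.0,
) -> Path:
    """Render the surface to an image file (extension selects the format).

    The z-axis is fixed to [0, 1] so depressions are comparable between
    policies.  With ``interpolate`` the surface is bilinearly refined for
    visual smoothness; the raw nine values are always overlaid as points.
    Rendering is deterministic given the options (fixed viewpoint).
    """
    out = Path(out)
    fig = plt.figure(figsize=(6, 5))
    ax = fig.add_subplot(projection="3d")
    xx3, yy3 = np.meshgrid([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    if interpolate:
        xx, yy, zz = _bilinear_refine(matrix.cells, refine)
    else:
        xx, yy, zz = xx3, yy3, matrix.cells
    ax.plot_surface(xx, yy, zz, cmap=cmap, vmin=0.0, vmax=1.0,
                    linewidth=0.2, edgecolor="none", alpha=0.9)
    ax.scatter(xx3.ravel(), yy3.ravel(), matrix.cells.ravel(),
               color="black", s=18, depthshade=False)
    if annotate_min:
        r, c = np.unravel_index(np.argmin(matrix.cells), (3, 3))
        ax.text(c + 1, r + 1, matrix.cells[r, c],
                f"  min {_LAYOUT[r][c]}={matrix.cells[r, c]:.3g}", fontsize=8)
    ax.set_zlim(0.0, 1.0)
    ax.set_xticks([1, 2, 3])
    ax.set_yticks([1, 2, 3])
    ax.set_xlabel("column")
    ax.set_ylabel("row")
    ax.set_zlabel("score")
    title = matrix.policy_id
    if matrix.grade:
        title += f" (grade {matrix.grade})"
    ax.set_title(f"PMC surface — {title}")
    ax.view_init(elev=elev, azim=azim)
    try:
        fig.savefig(out, dpi=120)
    except OSError as exc:
        raise OSError(f"cannot write surface image to {out}: {exc}") from exc
    finally:
        plt.close(fig)
    return out
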