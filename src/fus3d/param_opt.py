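"""Grid-search optimization of the hybrid-model parameters (T_res, ε, β).

Every (T_res, ε, β) triple (β1 = β2 tied) is run as a full segmentation
of one representative image from one fixed seed contour, scored by
Hausdorff distance or MAD against a reference boundary.  Logarithmic
default grids cover three decades per parameter; the minimum of the
chosen criterion over converged runs picks the optimum, with ties
broken toward smaller T_res (the switch fires earlier, which is
cheaper), then smaller β, then smaller ε.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .contours import Contour
from .errors import SegmentationError
from .levelset import SegParams, evolve, init_phi, prepare_forces
from .metrics import boundary_error
from .phantom import ImageFrame

T_RES_GRID = (5.0, 20.0, 50.0, 125.6, 315.5, 792.4, 1990.5, 5000.0)
EPSILON_GRID = (0.1, 0.21, 0.46, 1.0, 2.15, 4.64, 10.0, 21.54, 46.42, 100.0)
BETA_GRID = (0.6, 1.29, 2.79, 6.0, 12.92, 27.85, 60.0, 129.27, 278.50, 600.0)


@dataclass(frozen=True)
class ParamGrid:
    t_res_values: tuple[float, ...] = T_RES_GRID
    epsilon_values: tuple[float, ...] = EPSILON_GRID
    beta_values: tuple[float, ...] = BETA_GRID

    def __len__(self) -> int:
        return len(self.t_res_values) * len(self.epsilon_values) * len(self.beta_values)


@dataclass
class OptResult:
    best_params: SegParams
    best_hausdorff: float  # mm
    best_mad: float        # mm
    error_surface: pd.DataFrame  # columns: t_res, epsilon, beta, hausdorff, mad, converged


def optimize_params(image, reference: Contour, seed: Contour,
                    grid: ParamGrid | None = None,
                    criterion: str = "hausdorff",
                    base: SegParams | None = None,
                    spacing: float = 1.0,
                    plateau_tol_px: float = 0.5) -> OptResult:
    """Exhaustive grid search of (T_res, ε, β) against a reference boundary.

    ``image`` may be an ImageFrame or a raw 2D array; ``spacing`` (mm/px)
    is taken from the frame when one is given.  Edge maps and the GVF
    field depend only on (σ, α) and are computed once for all cells.
    Failed or diverged runs are recorded with infinite error.

    The error surface is typically flat near its minimum: cells whose
    criterion lies within ``plateau_tol_px`` (in pixels, converted with
    ``spacing``) of the best converged cell are treated as equivalent —
    differences below about half a pixel are contour-extraction noise —
    and the cheapest equivalent cell is selected: smallest T_res (the
    switch fires earlier), then smallest β, then smallest ε.
    """
    if criterion not in ("hausdorff", "mad"):
        raise ValueError("criterion must be 'hausdorff' or 'mad'")
    if isinstance(image, ImageFrame):
        spacing = float(np.mean(image.pixel_spacing))
        pixels = image.pixels
    else:
        pixels = np.asarray(image)
    if reference is None or len(reference) < 3:
        raise ValueError("invalid reference boundary")
    grid = grid or ParamGrid()
    base = base or SegParams()

    edge, field = prepare_forces(pixels, base)
    state0 = init_phi(pixels.shape, seed)  # validates the seed once

    rows = []
    for t_res in grid.t_res_values:
        for eps in grid.epsilon_values:
            for beta in grid.beta_values:
                params = replace(base, t_res=t_res, epsilon=eps, beta1=beta, beta2=beta)
                try:
                    _, contour = evolve(_fresh_state(state0), edge, field, params)
                    err = boundary_error(contour, reference, spacing)
                    rows.append(dict(t_res=t_res, epsilon=eps, beta=beta,
                                     hausdorff=err.hausdorff, mad=err.mad, converged=True))
                except (SegmentationError, ValueError):
                    rows.append(dict(t_res=t_res, epsilon=eps, beta=beta,
                                     hausdorff=np.inf, mad=np.inf, converged=False))
    surface = pd.DataFrame(rows)

    min_err = surface[criterion].min()
    if not np.isfinite(min_err):
        raise SegmentationError("every grid cell failed to segment")
    eligible = surface[surface[criterion] <= min_err + plateau_tol_px * spacing]
    best = eligible.sort_values(["t_res", "beta", "epsilon", criterion],
                                kind="stable").iloc[0]
    best_params = replace(base, t_res=float(best.t_res), epsilon=float(best.epsilon),
                          beta1=float(best.beta), beta2=float(best.beta))
    return OptResult(best_params=best_params,
                     best_hausdorff=float(best.hausdorff),
                     best_mad=float(best.mad),
                     error_surface=surface)


def _fresh_state(state):
    from .levelset import LevelSetState
    return LevelSetState(phi=state.phi.copy(), switch_on=state.switch_on,
                         iter=0, zero_set_mean_f=state.zero_set_mean_f)
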