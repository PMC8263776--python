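"""Mander's-coefficient colocalization and exponential dose-response fitting.

Mander's coefficients quantify, per channel, the fraction of fluorescence
residing in pixels where the other channel is above threshold:

    M1 = sum(A_i; B_i > t_B) / sum(A_i)    (within the cell mask)
    M2 = sum(B_i; A_i > t_A) / sum(B_i)

Thresholds default to per-channel Otsu within the cell mask; zero-threshold
and fixed-value modes are available.  The intensity-product overlap
coefficient R is reported as a secondary statistic because the plain term
"overlap coefficient" is used ambiguously in the literature.

The dose-response analysis mirrors how endoplasmic-reticulum residence of a
reporter responds to a co-expressed soluble regulator:
per cell, the regulator/reporter expression ratio (x) is paired with the
reporter's ER colocalization (y, an M1 value), and y(x) is fit with an
exponential decay A·exp(−k·x) + C by bounded nonlinear least squares.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from skimage.filters import threshold_otsu

__all__ = [
    "ColocImageSet",
    "ColocResult",
    "DecayFit",
    "manders_coefficients",
    "per_cell_ratio_analysis",
    "analyze_panel",
    "fit_exponential_decay",
]


@dataclass(frozen=True)
class ColocImageSet:
    """Named single-frame channels of one cell plus its mask.

    ``acquisition_tag`` identifies the imaging settings (laser intensity,
    photomultiplier gain); ratio analyses require every cell of a batch to
    share one tag, since raw intensities are only comparable at matched
    settings.
    """

    channels: dict[str, np.ndarray]
    cell_mask: np.ndarray
    cell_id: str = "cell"
    acquisition_tag: str = "batch-0"
    thresholds: dict[str, float] | None = None

    def __post_init__(self) -> None:
        mask = np.asarray(self.cell_mask, dtype=bool)
        if not mask.any():
            raise ValueError("cell mask is empty")
        object.__setattr__(self, "cell_mask", mask)
        chans = {}
        for name, img in self.channels.items():
            arr = np.asarray(img, dtype=float)
            if arr.shape != mask.shape:
                raise ValueError(f"channel {name!r} does not match the cell mask shape")
            chans[name] = arr
        object.__setattr__(self, "channels", chans)


@dataclass(frozen=True)
class ColocResult:
    cell_id: str
    m1: float
    m2: float
    overlap_r: float
    threshold_a: float
    threshold_b: float
    threshold_method: str


@dataclass(frozen=True)
class DecayFit:
    amplitude: float
    rate: float
    offset: float
    r_squared: float
    n_cells: int
    flat: bool = False


def _threshold(values: np.ndarray, method) -> float:
    if isinstance(method, (int, float)):
        return float(method)
    if method == "zero":
        return 0.0
    if method == "otsu":
        if np.ptp(values) == 0:
            return float(values.min())
        return float(threshold_otsu(values))
    raise ValueError(f"unknown threshold method {method!r}")


def manders_coefficients(
    image_set: ColocImageSet, ch_a: str, ch_b: str, threshold_method="otsu"
) -> ColocResult:
    """Mander's M1/M2 for a channel pair within the cell mask.

    ``threshold_method`` is ``"otsu"`` (per-channel Otsu inside the mask),
    ``"zero"``, or a fixed numeric threshold applied to both channels.
    """
    for name in (ch_a, ch_b):
        if name not in image_set.channels:
            raise ValueError(f"channel {name!r} missing")
    mask = image_set.cell_mask
    a = image_set.channels[ch_a][mask]
    b = image_set.channels[ch_b][mask]
    sum_a, sum_b = float(a.sum()), float(b.sum())
    if sum_a <= 0 or sum_b <= 0:
        raise ValueError("zero total intensity in a channel")
    t_a = _threshold(a, threshold_method)
    t_b = _threshold(b, threshold_method)
    m1 = float(a[b > t_b].sum()) / sum_a
    m2 = float(b[a > t_a].sum()) / sum_b
    denom = float(np.sqrt((a**2).sum() * (b**2).sum()))
    overlap_r = float((a * b).sum()) / denom if denom > 0 else 0.0
    return ColocResult(
        cell_id=image_set.cell_id,
        m1=m1,
        m2=m2,
        overlap_r=overlap_r,
        threshold_a=t_a,
        threshold_b=t_b,
        threshold_method=str(threshold_method),
    )


def per_cell_ratio_analysis(
    image_set: ColocImageSet,
    reporter: str = "reporter",
    er_channel: str = "marker",
    regulator: str = "regulator",
    threshold_method="otsu",
) -> tuple[float, float]:
    """One (x, y) point of the dose-response scatter for a single cell.

    x is the regulator/reporter ratio of mean intensities within the cell
    mask; y is the reporter's M1 against the ER channel.
    """
    for name in (reporter, er_channel, regulator):
        if name not in image_set.channels:
            raise ValueError(f"channel {name!r} missing")
    mask = image_set.cell_mask
    mean_rep = float(image_set.channels[reporter][mask].mean())
    if mean_rep <= 0:
        raise ValueError("reporter channel has no signal in the cell mask")
    ratio = float(image_set.channels[regulator][mask].mean()) / mean_rep
    er_coloc = manders_coefficients(image_set, reporter, er_channel, threshold_method).m1
    return ratio, er_coloc


def analyze_panel(image_sets, threshold_method="otsu", **channel_names):
    """Dose-response points for a batch of cells imaged at matched settings.

    Raises if the cells carry different acquisition tags — raw-intensity
    ratios are not comparable across changed gain or laser settings.
    """
    sets = list(image_sets)
    if not sets:
        raise ValueError("empty panel")
    tags = {s.acquisition_tag for s in sets}
    if len(tags) > 1:
        raise ValueError(f"mixed acquisition settings in one panel: {sorted(tags)}")
    return [
        per_cell_ratio_analysis(s, threshold_method=threshold_method, **channel_names)
        for s in sets
    ]


def fit_exponential_decay(points, with_offset: bool = True) -> DecayFit:
    """Fit y = A·exp(−k·x) + C to dose-response points by least squares.

    Bounds keep A, k non-negative and C in [0, 1]; five deterministic starts
    (rate spread over decades) guard against local minima, and the
    best-SSE solution is returned.  A constant-y input yields a flat fit
    (k at the zero boundary, R² = 0) flagged as such.
    """
    pts = np.asarray(list(points), dtype=float)
    if pts.ndim == 2 and pts.shape[1] == 2:
        x, y = pts[:, 0], pts[:, 1]
    else:
        raise ValueError("points must be (x, y) pairs")
    if len(x) < 4:
        raise ValueError("need at least 4 points for the decay fit")
    if np.any(x < 0):
        raise ValueError("ratios must be non-negative")
    if np.ptp(x) == 0:
        raise ValueError("degenerate predictor: all x equal")

    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        return DecayFit(amplitude=0.0, rate=0.0, offset=float(np.clip(y[0], 0, 1)),
                        r_squared=0.0, n_cells=len(x), flat=True)

    span = max(float(np.ptp(y)), 1e-6)
    c0 = float(np.clip(y.min(), 0.0, 1.0))
    x_scale = max(float(x.max()), 1e-6)

    def residuals(theta):
        a, k, c = theta if with_offset else (*theta, 0.0)
        return a * np.exp(-k * x) + c - y

    best = None
    for k0 in np.geomspace(0.1, 10.0, 5) / x_scale:
        theta0 = [span, k0, c0] if with_offset else [span, k0]
        lb = [0.0, 0.0, 0.0] if with_offset else [0.0, 0.0]
        ub = [np.inf, np.inf, 1.0] if with_offset else [np.inf, np.inf]
        sol = least_squares(residuals, theta0, bounds=(lb, ub), xtol=1e-14, ftol=1e-14, gtol=1e-14)
        sse = float((sol.fun**2).sum())
        if best is None or sse < best[0]:
            best = (sse, sol)
    sse, sol = best
    a, k, c = sol.x if with_offset else (*sol.x, 0.0)
    r2 = 1.0 - sse / ss_tot
    return DecayFit(
        amplitude=float(a), rate=float(k), offset=float(c),
        r_squared=float(r2), n_cells=len(x), flat=bool(k < 1e-9),
    )
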