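"""Truth-tagged synthetic data for every analysis stage.

Single-molecule subunit counting rests on a simple generative picture: a
surface-immobilized oligomer with ``n`` subunits carries ``n`` GFP tags, each
of which matured into a fluorescent state independently with probability
``p``.  The number of fluorophores per diffraction-limited spot is therefore
Binomial(n, p); each fluorophore then photobleaches after an exponentially
distributed exposure time, so the summed ROI intensity of a spot is a
staircase that descends one unit per bleaching event.  Spots with zero
fluorescent tags are invisible, which is why downstream inference conditions
on at least one fluorophore.

This module draws those populations, renders them into TIRF-like movies
(integrated-Gaussian point-spread profiles on a constant background), and
generates matching image sets for acceptor-photobleaching FRET and for the
colocalization dose-response analysis (endoplasmic-reticulum residence of a
reporter decaying exponentially with the expression ratio of a co-expressed
regulator).  Every generator records its
ground truth so that each downstream stage can be audited end to end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import ndtr

__all__ = [
    "SimConfig",
    "SpotTruth",
    "SpotTruthTable",
    "FretTruth",
    "FretGeometry",
    "FretImageBundle",
    "ColocTruth",
    "ColocPanelConfig",
    "simulate_spot_population",
    "simulate_traces",
    "resolvable_step_count",
    "render_movie",
    "simulate_fret_pair",
    "simulate_coloc_panel",
]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the single-spot bleaching simulation.

    Parameters
    ----------
    seed
        Seed for the pseudo-random stream; identical configs give
        bit-identical output.
    n_subunits
        True subunit count ``n`` of the simulated oligomer (1 for a monomer,
        2 for a dimer, 4 for a tetrameric channel).
    p_fluor
        Probability ``p`` that a given GFP tag is fluorescent
        (folded/matured).
    n_spots
        Number of complexes placed in the field, including dark ones.
    n_frames, frame_interval
        Movie length in frames and the frame spacing in seconds.
    unit_intensity
        Summed-ROI intensity contributed by one fluorophore (a.u.).
    bleach_mean_time
        Mean of the exponential single-fluorophore bleach-time distribution
        (seconds).
    noise_sd
        Gaussian noise standard deviation: added per frame to directly
        simulated trace sums, and per pixel to rendered movie frames (a.u.).
    background_level
        Background per pixel (a.u.); a directly simulated trace carries
        ``background_level * roi_size**2``.
    image_shape
        Movie frame shape ``(rows, cols)`` in pixels.
    psf_sigma
        Standard deviation of the isotropic Gaussian point-spread function
        (pixels).
    min_spot_separation
        Minimum pairwise distance between spot centers (pixels); keeps the
        density low enough that one spot holds one complex.
    roi_size
        Side of the square summed-intensity ROI (pixels).
    poisson_noise
        If True, pixel/trace values are Poisson-sampled around their mean
        instead of carrying additive Gaussian noise.
    blink_rate
        Expected number of spurious one-frame upward blips injected per
        trace; stress-test switch for the step detector, default off.
    drift_px_per_movie
        Optional linear drift of every spot over the whole movie (pixels);
        used to exercise the immobility filter.
    """

    seed: int = 0
    n_subunits: int = 2
    p_fluor: float = 0.67
    n_spots: int = 100
    n_frames: int = 200
    frame_interval: float = 0.1
    unit_intensity: float = 100.0
    bleach_mean_time: float = 4.0
    noise_sd: float = 0.0
    background_level: float = 10.0
    image_shape: tuple[int, int] = (128, 128)
    psf_sigma: float = 1.2
    min_spot_separation: float = 8.0
    roi_size: int = 6
    poisson_noise: bool = False
    blink_rate: float = 0.0
    drift_px_per_movie: float = 0.0

    def __post_init__(self) -> None:
        checks = [
            ("n_subunits", self.n_subunits >= 1),
            ("p_fluor", 0.0 <= self.p_fluor <= 1.0 and math.isfinite(self.p_fluor)),
            ("n_spots", self.n_spots >= 1),
            ("n_frames", self.n_frames >= 2),
            ("frame_interval", self.frame_interval > 0 and math.isfinite(self.frame_interval)),
            ("unit_intensity", self.unit_intensity > 0 and math.isfinite(self.unit_intensity)),
            ("bleach_mean_time", self.bleach_mean_time > 0 and math.isfinite(self.bleach_mean_time)),
            ("noise_sd", self.noise_sd >= 0 and math.isfinite(self.noise_sd)),
            ("background_level", self.background_level >= 0 and math.isfinite(self.background_level)),
            ("psf_sigma", self.psf_sigma > 0 and math.isfinite(self.psf_sigma)),
            ("roi_size", self.roi_size >= 3),
            ("min_spot_separation", self.min_spot_separation > 2 * self.psf_sigma),
            ("blink_rate", self.blink_rate >= 0),
        ]
        for name, ok in checks:
            if not ok:
                raise ValueError(f"SimConfig field {name!r} is out of range: {getattr(self, name)!r}")


@dataclass(frozen=True)
class SpotTruth:
    """Ground truth for one simulated spot."""

    spot_id: int
    position: tuple[float, float]  # (row, col), 0-based
    n_fluorescent: int
    bleach_times: tuple[float, ...]  # seconds, one per fluorescent tag

    @property
    def visible(self) -> bool:
        return self.n_fluorescent >= 1


@dataclass(frozen=True)
class SpotTruthTable:
    """All spot truths of one simulated field plus the config that made them."""

    spots: tuple[SpotTruth, ...]
    config: SimConfig

    def __len__(self) -> int:
        return len(self.spots)

    def __iter__(self):
        return iter(self.spots)

    @property
    def visible_spots(self) -> tuple[SpotTruth, ...]:
        return tuple(s for s in self.spots if s.visible)

    def to_frame(self):
        """Truth table as a pandas DataFrame (one row per spot)."""
        import pandas as pd

        return pd.DataFrame(
            {
                "spot_id": [s.spot_id for s in self.spots],
                "row": [s.position[0] for s in self.spots],
                "col": [s.position[1] for s in self.spots],
                "n_fluorescent": [s.n_fluorescent for s in self.spots],
                "visible": [s.visible for s in self.spots],
                "bleach_times": [";".join(f"{t:.6f}" for t in s.bleach_times) for s in self.spots],
            }
        )


# ---------------------------------------------------------------------------
# spot population and traces
# ---------------------------------------------------------------------------


def _place_spots(rng: np.random.Generator, config: SimConfig) -> np.ndarray:
    """Dart-throwing placement honoring the minimum pairwise separation."""
    nrow, ncol = config.image_shape
    margin = config.roi_size / 2 + 1.0
    if nrow - 2 * margin <= 0 or ncol - 2 * margin <= 0:
        raise ValueError("image_shape too small for the ROI margin")
    sep = config.min_spot_separation
    min_sep2 = sep * sep
    # spatial hash: only neighbors within one separation radius need checking
    cell = sep
    grid: dict[tuple[int, int], list[tuple[float, float]]] = {}
    positions: list[tuple[float, float]] = []
    max_tries = 200 * config.n_spots
    tries = 0
    while len(positions) < config.n_spots:
        if tries >= max_tries:
            raise RuntimeError(
                f"could not place {config.n_spots} spots with separation "
                f"{config.min_spot_separation} px in {config.image_shape}; field too crowded"
            )
        tries += 1
        r = rng.uniform(margin, nrow - margin)
        c = rng.uniform(margin, ncol - margin)
        gi, gj = int(r // cell), int(c // cell)
        ok = True
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                for pr, pc in grid.get((gi + di, gj + dj), ()):
                    if (r - pr) ** 2 + (c - pc) ** 2 < min_sep2:
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                break
        if ok:
            positions.append((r, c))
            grid.setdefault((gi, gj), []).append((r, c))
    return np.asarray(positions)


def simulate_spot_population(config: SimConfig, include_dark: bool = False):
    """Draw a spot population and its summed-ROI bleaching traces.

    Per spot the fluorophore count is Binomial(``n_subunits``, ``p_fluor``)
    and each fluorophore bleaches after an independent Exp(``bleach_mean_time``)
    time.  The trace at frame ``t`` is
    ``unit_intensity * (fluorophores surviving at t·frame_interval) +
    background + noise``; emitted traces are background-corrected with the
    subtracted constant recorded on the trace.

    Parameters
    ----------
    config
        Simulation parameters (validated on construction).
    include_dark
        Also emit (flat) traces for invisible spots; by default only spots
        with at least one fluorescent tag produce a trace, mirroring what an
        experiment can see.

    Returns
    -------
    (SpotTruthTable, list of BleachTrace)
    """
    from .traces import BleachTrace

    rng = np.random.default_rng(config.seed)
    positions = _place_spots(rng, config)
    counts = rng.binomial(config.n_subunits, config.p_fluor, size=config.n_spots)
    spots = []
    for i in range(config.n_spots):
        k = int(counts[i])
        times = tuple(float(t) for t in rng.exponential(config.bleach_mean_time, size=k))
        spots.append(
            SpotTruth(
                spot_id=i,
                position=(float(positions[i, 0]), float(positions[i, 1])),
                n_fluorescent=k,
                bleach_times=times,
            )
        )
    truth = SpotTruthTable(spots=tuple(spots), config=config)

    t_frames = np.arange(config.n_frames) * config.frame_interval
    bg = config.background_level * config.roi_size**2
    traces = []
    for spot in truth:
        if not spot.visible and not include_dark:
            continue
        if spot.n_fluorescent:
            bt = np.asarray(spot.bleach_times)
            surviving = (bt[None, :] > t_frames[:, None]).sum(axis=1)
        else:
            surviving = np.zeros(config.n_frames, dtype=int)
        mean = config.unit_intensity * surviving + bg
        if config.blink_rate > 0:
            n_blips = rng.poisson(config.blink_rate)
            for _ in range(n_blips):
                mean = mean.astype(float, copy=True)
                mean[rng.integers(config.n_frames)] += config.unit_intensity
        if config.poisson_noise:
            values = rng.poisson(mean).astype(float)
        elif config.noise_sd > 0:
            values = mean + rng.normal(0.0, config.noise_sd, size=config.n_frames)
        else:
            values = mean.astype(float)
        traces.append(
            BleachTrace(
                values=values - bg,
                frame_interval=config.frame_interval,
                spot_id=spot.spot_id,
                background_per_frame=bg,
            )
        )
    return truth, traces


def simulate_traces(config: SimConfig, n_visible: int | None = None):
    """Convenience wrapper returning only visible-spot traces.

    If ``n_visible`` is given, the spot count is inflated (and the population
    re-drawn with ``n_spots`` adjusted) until at least that many visible
    spots exist, then truncated to exactly ``n_visible`` traces.  Useful when
    an experiment is defined by its number of analyzable spots.
    """
    if n_visible is None:
        return simulate_spot_population(config)
    p_vis = 1.0 - (1.0 - config.p_fluor) ** config.n_subunits
    if p_vis <= 0:
        raise ValueError("no spot can be visible at p_fluor = 0")
    n_spots = max(int(n_visible / p_vis * 1.3) + 10, n_visible)
    # widen the field so the separation constraint stays satisfiable
    area_per_spot = (2 * config.min_spot_separation) ** 2
    side = int(np.sqrt(n_spots * area_per_spot) * 1.3) + 2 * (config.roi_size + 2)
    cfg = replace(config, n_spots=n_spots, image_shape=(side, side))
    while True:
        truth, traces = simulate_spot_population(cfg)
        if len(traces) >= n_visible:
            return truth, traces[:n_visible]
        cfg = replace(cfg, n_spots=int(cfg.n_spots * 1.5) + 10)


def resolvable_step_count(spot: SpotTruth, config: SimConfig) -> int:
    """Number of bleaching steps resolvable at the movie's frame rate.

    Fluorophores bleaching within the same frame interval produce a single
    larger step, and a fluorophore outliving the movie produces none; the
    resolvable count is the number of distinct frames at which the surviving
    count drops.  This is the fair ground truth for a step detector, which
    cannot see below the frame rate.
    """
    frames = {
        math.ceil(bt / config.frame_interval)
        for bt in spot.bleach_times
        if bt < (config.n_frames - 1) * config.frame_interval
    }
    return len(frames - {0})


# ---------------------------------------------------------------------------
# movie rendering
# ---------------------------------------------------------------------------


def _pixel_gaussian_mass(center: float, sigma: float, n: int) -> np.ndarray:
    """Integral of a 1-D unit Gaussian over each pixel ``[i-0.5, i+0.5)``."""
    edges = np.arange(n + 1) - 0.5
    cdf = ndtr((edges - center) / sigma)
    return np.diff(cdf)


def render_movie(truth: SpotTruthTable, config: SimConfig | None = None):
    """Render a truth table into a :class:`~oligotrace.traces.MovieStack`.

    Each surviving fluorophore deposits ``unit_intensity`` a.u. through an
    isotropic Gaussian PSF, integrated exactly over pixel areas; frames share
    a constant per-pixel background, with optional Gaussian or Poisson noise.
    A nonzero ``drift_px_per_movie`` translates every spot linearly along the
    column axis over the movie, for immobility-filter tests.
    """
    from .traces import MovieStack

    config = config or truth.config
    nrow, ncol = config.image_shape
    frames = np.full((config.n_frames, nrow, ncol), float(config.background_level))
    t_frames = np.arange(config.n_frames) * config.frame_interval
    drift_per_frame = config.drift_px_per_movie / max(config.n_frames - 1, 1)
    for spot in truth:
        if not spot.visible:
            continue
        bt = np.asarray(spot.bleach_times)
        surviving = (bt[None, :] > t_frames[:, None]).sum(axis=1)
        r0, c0 = spot.position
        if drift_per_frame == 0.0:
            rowm = _pixel_gaussian_mass(r0, config.psf_sigma, nrow)
            colm = _pixel_gaussian_mass(c0, config.psf_sigma, ncol)
            psf = np.outer(rowm, colm)
            frames += config.unit_intensity * surviving[:, None, None] * psf[None, :, :]
        else:
            for t in range(config.n_frames):
                if surviving[t] == 0:
                    continue
                c = c0 + drift_per_frame * t
                rowm = _pixel_gaussian_mass(r0, config.psf_sigma, nrow)
                colm = _pixel_gaussian_mass(c, config.psf_sigma, ncol)
                frames[t] += config.unit_intensity * surviving[t] * np.outer(rowm, colm)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    if config.poisson_noise:
        frames = rng.poisson(frames).astype(float)
    elif config.noise_sd > 0:
        frames = frames + rng.normal(0.0, config.noise_sd, size=frames.shape)
    return MovieStack(data=frames, frame_interval=config.frame_interval)


# ---------------------------------------------------------------------------
# FRET image pairs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FretTruth:
    """Ground truth of one acceptor-photobleaching FRET experiment.

    ``E_true`` is the energy-transfer efficiency; ``bleach_depth_true`` the
    achieved acceptor bleach fraction β (about 0.8 in practice);
    ``scan_loss_true`` the whole-cell donor loss per acquisition caused by
    scanning; ``donor_unquenched`` the donor intensity with no acceptor.
    """

    E_true: float
    bleach_depth_true: float = 0.8
    scan_loss_true: float = 0.0
    donor_unquenched: float = 1000.0
    acceptor_level: float = 800.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.E_true < 1.0):
            raise ValueError(f"E_true must be in [0, 1), got {self.E_true}")
        if not (0.0 <= self.bleach_depth_true <= 1.0):
            raise ValueError(f"bleach_depth_true must be in [0, 1], got {self.bleach_depth_true}")
        if not (0.0 <= self.scan_loss_true < 1.0):
            raise ValueError(f"scan_loss_true must be in [0, 1), got {self.scan_loss_true}")


@dataclass(frozen=True)
class FretGeometry:
    """Image shape and the bleached / unbleached-control regions."""

    shape: tuple[int, int] = (64, 64)
    bleach_roi: np.ndarray | None = None  # bool mask; default: left half
    control_roi: np.ndarray | None = None  # bool mask; default: right quarter

    def masks(self) -> tuple[np.ndarray, np.ndarray]:
        nrow, ncol = self.shape
        bleach = self.bleach_roi
        control = self.control_roi
        if bleach is None:
            bleach = np.zeros(self.shape, dtype=bool)
            bleach[:, : ncol // 2] = True
        if control is None:
            control = np.zeros(self.shape, dtype=bool)
            control[:, 3 * ncol // 4 :] = True
        bleach = np.asarray(bleach, dtype=bool)
        control = np.asarray(control, dtype=bool)
        if bleach.shape != self.shape or control.shape != self.shape:
            raise ValueError("ROI masks must match the image shape")
        if not bleach.any() or not control.any():
            raise ValueError("ROI masks must be nonempty")
        if (bleach & control).any():
            raise ValueError("bleach and control ROIs must be disjoint")
        return bleach, control


def simulate_fret_pair(truth: FretTruth, geometry: FretGeometry | None = None,
                       noise_sd: float = 0.0, seed: int = 0, cell_id: str = "cell"):
    """Generate pre/post-bleach donor and acceptor images for one cell.

    Generative model: the donor is quenched by transfer, so its pre-bleach
    mean is ``donor_unquenched * (1 − E)``.  Bleaching a fraction β of the
    acceptor inside the bleach ROI removes that share of the transfer there,
    giving a post-bleach donor mean ``donor_unquenched * (1 − E(1−β))``;
    every post image is additionally scaled by ``(1 − scan_loss)`` across the
    whole cell.  Outside the bleach ROI the donor changes only by scan loss.
    """
    from .fret import FretImageSet

    geometry = geometry or FretGeometry()
    bleach, control = geometry.masks()
    rng = np.random.default_rng(seed)
    E, beta = truth.E_true, truth.bleach_depth_true
    keep = 1.0 - truth.scan_loss_true

    donor_pre = np.full(geometry.shape, truth.donor_unquenched * (1.0 - E))
    donor_post = np.where(
        bleach,
        truth.donor_unquenched * (1.0 - E * (1.0 - beta)) * keep,
        truth.donor_unquenched * (1.0 - E) * keep,
    )
    acceptor_pre = np.full(geometry.shape, truth.acceptor_level)
    acceptor_post = np.where(bleach, truth.acceptor_level * (1.0 - beta), truth.acceptor_level)
    if noise_sd > 0:
        donor_pre = donor_pre + rng.normal(0, noise_sd, geometry.shape)
        donor_post = donor_post + rng.normal(0, noise_sd, geometry.shape)
        acceptor_pre = acceptor_pre + rng.normal(0, noise_sd, geometry.shape)
        acceptor_post = acceptor_post + rng.normal(0, noise_sd, geometry.shape)
    return FretImageSet(
        donor_pre=donor_pre,
        donor_post=donor_post,
        acceptor_pre=acceptor_pre,
        acceptor_post=acceptor_post,
        bleach_roi=bleach,
        control_roi=control,
        cell_id=cell_id,
    )


# ---------------------------------------------------------------------------
# colocalization panels
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ColocTruth:
    """Ground truth for one simulated cell of the dose-response panel.

    The fraction of the reporter residing on the ER mask is
    ``A * exp(-k * ratio) + C`` where ``ratio`` is the regulator/reporter
    expression ratio; the remainder sits on the membrane mask.
    """

    regulator_level: float
    decay_amplitude: float = 0.9
    decay_rate: float = 1.5
    decay_offset: float = 0.0
    er_mask: np.ndarray | None = None
    mb_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.decay_amplitude < 0 or self.decay_rate < 0:
            raise ValueError("decay amplitude and rate must be non-negative")
        if not (0.0 <= self.decay_offset <= 1.0):
            raise ValueError("decay offset must be in [0, 1]")
        if self.regulator_level < 0:
            raise ValueError("regulator_level must be non-negative")


@dataclass(frozen=True)
class ColocPanelConfig:
    """Shared acquisition settings of a simulated colocalization batch."""

    shape: tuple[int, int] = (64, 64)
    reporter_level: float = 100.0  # mean reporter intensity over the cell mask
    marker_level: float = 200.0  # ER-marker intensity on its mask
    noise_sd: float = 0.0
    seed: int = 0
    acquisition_tag: str = "batch-0"


def _default_masks(shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Concentric 'cell': inner disc = ER, surrounding ring = membrane."""
    nrow, ncol = shape
    rr, cc = np.mgrid[0:nrow, 0:ncol]
    r2 = (rr - (nrow - 1) / 2) ** 2 + (cc - (ncol - 1) / 2) ** 2
    inner = min(nrow, ncol) * 0.22
    outer = min(nrow, ncol) * 0.42
    er = r2 <= inner**2
    mb = (r2 > (outer - 2) ** 2) & (r2 <= outer**2)
    return er, mb


def simulate_coloc_panel(truths, config: ColocPanelConfig | None = None):
    """Generate one ColocImageSet per cell truth.

    Per cell, the reporter's total intensity is split between the ER and
    membrane masks according to the exponential dose-response; the ER-marker
    channel labels the ER mask; the regulator channel is uniform over the
    cell at ``regulator_level``.  All cells of a panel share acquisition
    settings, mirroring a matched-gain imaging session.
    """
    from .coloc import ColocImageSet

    config = config or ColocPanelConfig()
    rng = np.random.default_rng(config.seed)
    image_sets = []
    for i, truth in enumerate(truths):
        er = truth.er_mask
        mb = truth.mb_mask
        if er is None or mb is None:
            er, mb = _default_masks(config.shape)
        er = np.asarray(er, dtype=bool)
        mb = np.asarray(mb, dtype=bool)
        if not er.any() or not mb.any():
            raise ValueError("ER and membrane masks must be nonempty")
        if (er & mb).any():
            raise ValueError("ER and membrane masks must be disjoint")
        cell = er | mb
        n_cell = int(cell.sum())
        total = config.reporter_level * n_cell
        ratio = truth.regulator_level / config.reporter_level
        frac_er = truth.decay_amplitude * math.exp(-truth.decay_rate * ratio) + truth.decay_offset
        frac_er = min(max(frac_er, 0.0), 1.0)

        reporter = np.zeros(er.shape)
        reporter[er] = frac_er * total / er.sum()
        reporter[mb] = (1.0 - frac_er) * total / mb.sum()
        marker = np.where(er, config.marker_level, 0.0)
        regulator = np.where(cell, truth.regulator_level, 0.0)
        if config.noise_sd > 0:
            reporter = reporter + rng.normal(0, config.noise_sd, er.shape)
            marker = marker + rng.normal(0, config.noise_sd, er.shape)
            regulator = regulator + rng.normal(0, config.noise_sd, er.shape)
        image_sets.append(
            ColocImageSet(
                channels={"reporter": reporter, "marker": marker, "regulator": regulator},
                cell_mask=cell,
                cell_id=f"cell-{i}",
                acquisition_tag=config.acquisition_tag,
            )
        )
    return image_sets


@dataclass(frozen=True)
class FretImageBundle:
    """Filename bookkeeping for a FRET image set written to disk."""

    cell_id: str
    paths: dict = field(default_factory=dict)
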