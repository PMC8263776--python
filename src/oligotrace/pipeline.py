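"""End-to-end pipelines binding simulation, detection and inference.

Each pipeline returns a :class:`ReportBundle` holding machine-readable
results, plot-ready tables and a provenance block (config echo, seed,
package version, input digests); a bundle written twice from the same config
is byte-identical, which the test suite asserts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .synthetic import (
    SimConfig,
    FretTruth,
    FretGeometry,
    ColocTruth,
    ColocPanelConfig,
    simulate_traces,
    simulate_spot_population,
    render_movie,
    simulate_fret_pair,
    simulate_coloc_panel,
)
from .traces import DetectionParams, detect_immobile_spots, extract_trace, estimate_background
from .steps import StepFitParams, AcceptanceParams, fit_steps, accept_trace, count_distribution
from .stoichiometry import select_model, fit_mixture
from .fret import FretQCParams, compute_fret_efficiency, summarize_group
from .coloc import analyze_panel, fit_exponential_decay, manders_coefficients

__all__ = [
    "CountingConfig",
    "FretPipelineConfig",
    "ColocPipelineConfig",
    "ReportBundle",
    "run_counting_pipeline",
    "run_fret_pipeline",
    "run_coloc_pipeline",
]


# ---------------------------------------------------------------------------
# configs
# ---------------------------------------------------------------------------


def _from_dict(cls, data: dict):
    """Build a (possibly nested) config dataclass, rejecting unknown keys."""
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = {}
    for key, value in data.items():
        ftype = fields[key].type
        target = _NESTED.get((cls.__name__, key))
        if target is not None and isinstance(value, dict):
            value = _from_dict(target, value)
        elif isinstance(value, list):
            value = tuple(tuple(v) if isinstance(v, list) else v for v in value)
        kwargs[key] = value
    return cls(**kwargs)


@dataclass(frozen=True)
class CountingConfig:
    """Parameters of the subunit-counting pipeline."""

    sim: SimConfig = field(default_factory=SimConfig)
    n_visible: int | None = None
    use_movie: bool = False
    step_params: StepFitParams = field(default_factory=StepFitParams)
    accept_params: AcceptanceParams = field(default_factory=AcceptanceParams)
    detection: DetectionParams = field(default_factory=DetectionParams)
    candidates: tuple[int, ...] = (1, 2, 3, 4)
    fit_mixture_components: tuple[int, ...] | None = None

    @classmethod
    def from_dict(cls, data: dict) -> "CountingConfig":
        return _from_dict(cls, data)


@dataclass(frozen=True)
class FretPipelineConfig:
    e_true: tuple[float, ...] = (0.2,)
    bleach_depth: float = 0.8
    scan_loss: float = 0.0
    donor_unquenched: float = 1000.0
    noise_sd: float = 0.0
    seed: int = 0
    qc: FretQCParams = field(default_factory=FretQCParams)

    @classmethod
    def from_dict(cls, data: dict) -> "FretPipelineConfig":
        return _from_dict(cls, data)


@dataclass(frozen=True)
class ColocPipelineConfig:
    n_cells: int = 30
    decay_amplitude: float = 0.9
    decay_rate: float = 1.5
    decay_offset: float = 0.0
    regulator_max: float = 200.0
    panel: ColocPanelConfig = field(default_factory=ColocPanelConfig)
    with_offset: bool = True

    @classmethod
    def from_dict(cls, data: dict) -> "ColocPipelineConfig":
        return _from_dict(cls, data)


_NESTED = {
    ("CountingConfig", "sim"): SimConfig,
    ("CountingConfig", "step_params"): StepFitParams,
    ("CountingConfig", "accept_params"): AcceptanceParams,
    ("CountingConfig", "detection"): DetectionParams,
    ("FretPipelineConfig", "qc"): FretQCParams,
    ("ColocPipelineConfig", "panel"): ColocPanelConfig,
}


# ---------------------------------------------------------------------------
# report bundle
# ---------------------------------------------------------------------------


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(asdict(obj))
    if isinstance(obj, float) and (obj != obj or obj in (float("inf"), float("-inf"))):
        return repr(obj)
    return obj


@dataclass
class ReportBundle:
    """Results + tables + provenance of one pipeline run."""

    results: dict
    tables: dict[str, pd.DataFrame]
    provenance: dict

    def write(self, outdir) -> list[Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written = []
        report = {"results": _jsonable(self.results), "provenance": _jsonable(self.provenance)}
        path = outdir / "report.json"
        path.write_text(json.dumps(report, sort_keys=True, indent=2) + "\n")
        written.append(path)
        for name, table in self.tables.items():
            path = outdir / f"{name}.csv"
            table.to_csv(path, index=False)
            written.append(path)
        return written


def _provenance(config, input_paths=()) -> dict:
    digests = {}
    for p in input_paths:
        digests[str(p)] = hashlib.sha256(Path(p).read_bytes()).hexdigest()
    return {
        "config": _jsonable(config),
        "package_version": __version__,
        "input_digests": digests,
    }


# ---------------------------------------------------------------------------
# pipelines
# ---------------------------------------------------------------------------


def run_counting_pipeline(config: CountingConfig | None = None) -> ReportBundle:
    """Simulate (or render and re-extract) traces, count steps, infer n."""
    config = config or CountingConfig()
    if config.use_movie:
        truth, _ = simulate_spot_population(config.sim)
        movie = render_movie(truth, config.sim)
        rois = detect_immobile_spots(movie, config.detection)
        bg = estimate_background(movie, rois)
        traces = [
            extract_trace(movie, roi, background_per_frame=bg * roi.size**2, spot_id=i)
            for i, roi in enumerate(rois)
        ]
    else:
        truth, traces = simulate_traces(config.sim, n_visible=config.n_visible)

    fits = [accept_trace(fit_steps(t, config.step_params), config.accept_params) for t in traces]
    table = count_distribution(fits, k_max=config.accept_params.k_max)
    selection = select_model(table, candidates=config.candidates)

    results = {
        "step_counts": {str(k): v for k, v in sorted(table.counts.items())},
        "total_spots": table.total_spots,
        "n_traces": len(traces),
        "n_rejected": sum(not f.accepted for f in fits),
        "selected_n": selection.selected_n,
        "selection_margin": selection.selection_margin,
        "candidates": selection.candidates,
        "p_hat": selection.fits[selection.selected_n].model.p,
        "p_ci": selection.fits[selection.selected_n].p_ci,
    }
    if config.fit_mixture_components:
        mix = fit_mixture(table, components=config.fit_mixture_components)
        results["mixture"] = {
            "components": mix.components,
            "p": mix.p,
            "log_likelihood": mix.log_likelihood,
            "boundary": mix.boundary,
        }

    fit_rows = pd.DataFrame(
        {
            "spot_id": [f.spot_id for f in fits],
            "n_steps": [f.n_steps for f in fits],
            "accepted": [f.accepted for f in fits],
            "rejection_reason": [f.rejection_reason or "" for f in fits],
            "residual_sd": [f.residual_sd for f in fits],
        }
    )
    best = selection.fits[selection.selected_n]
    freq_rows = pd.DataFrame(
        {
            "k": list(range(1, table.k_max + 1)),
            "observed_freq": [table.frequency(k) for k in range(1, table.k_max + 1)],
            "expected_freq": [best.expected_freqs.get(k, 0.0) for k in range(1, table.k_max + 1)],
        }
    )
    return ReportBundle(
        results=results,
        tables={"step_fits": fit_rows, "frequencies": freq_rows},
        provenance=_provenance(config),
    )


def run_fret_pipeline(config: FretPipelineConfig | None = None) -> ReportBundle:
    """Simulate a batch of acceptor-photobleaching cells and summarize."""
    config = config or FretPipelineConfig()
    rows = []
    results_objs = []
    for i, e_true in enumerate(config.e_true):
        truth = FretTruth(
            E_true=e_true,
            bleach_depth_true=config.bleach_depth,
            scan_loss_true=config.scan_loss,
            donor_unquenched=config.donor_unquenched,
        )
        image_set = simulate_fret_pair(
            truth, FretGeometry(), noise_sd=config.noise_sd,
            seed=config.seed + i, cell_id=f"cell-{i}",
        )
        res = compute_fret_efficiency(image_set, config.qc)
        results_objs.append(res)
        rows.append(
            {
                "cell_id": res.cell_id,
                "E_true": e_true,
                "f_before": res.f_before,
                "f_after_corrected": res.f_after_corrected,
                "scan_factor": res.scan_factor,
                "bleach_depth": res.bleach_depth,
                "efficiency_pct": res.efficiency_pct,
                "efficiency_pct_canonical": res.efficiency_pct_canonical,
                "passed_qc": res.passed_qc,
            }
        )
    summary = summarize_group(results_objs, label="simulated")
    return ReportBundle(
        results={"group": summary},
        tables={"fret_cells": pd.DataFrame(rows)},
        provenance=_provenance(config),
    )


def run_coloc_pipeline(config: ColocPipelineConfig | None = None) -> ReportBundle:
    """Simulate a dose-response panel, measure colocalization, fit the decay."""
    config = config or ColocPipelineConfig()
    levels = np.linspace(0.0, config.regulator_max, config.n_cells)
    truths = [
        ColocTruth(
            regulator_level=float(lv),
            decay_amplitude=config.decay_amplitude,
            decay_rate=config.decay_rate,
            decay_offset=config.decay_offset,
        )
        for lv in levels
    ]
    panel = simulate_coloc_panel(truths, config.panel)
    points = analyze_panel(panel)
    fit = fit_exponential_decay(points, with_offset=config.with_offset)
    coloc_rows = []
    for s, (x, y) in zip(panel, points):
        res = manders_coefficients(s, "reporter", "marker")
        coloc_rows.append(
            {"cell_id": s.cell_id, "ratio": x, "er_coloc": y, "m1": res.m1, "m2": res.m2}
        )
    return ReportBundle(
        results={
            "decay_fit": {
                "amplitude": fit.amplitude,
                "rate": fit.rate,
                "offset": fit.offset,
                "r_squared": fit.r_squared,
                "n_cells": fit.n_cells,
                "flat": fit.flat,
            }
        },
        tables={"coloc_cells": pd.DataFrame(coloc_rows)},
        provenance=_provenance(config),
    )
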