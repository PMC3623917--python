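"""Config-driven orchestration of the multi-scale roughness analysis.

A run loads (or simulates) a set of energy trajectories, then for each
window exponent m and each time scale tau plans windows, computes per-window
statistics and aggregates them into one :class:`~pesrough.stats.ScaleSummary`
per scale.  Four output surfaces are written per exponent, mirroring the
standard presentation of this analysis:

* ``summary.tsv``     — one row per scale: mean r, mean sigmas, smoothing /
                        roughening probabilities, quadrant occupancy;
* ``histograms.json`` — r and sigma distributions per scale;
* ``windows_<s>.tsv`` — per-window (Delta_sigma, r) scatter dumps;
* figures (optional)  — advisory plots; TSV/JSON are the tested surface.

Scales the data cannot support are skipped with a logged warning so short
series still exercise the full pipeline.  Identical configs (including the
seed) reproduce identical TSV/JSON bytes.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import CapacityError, ValidationError
from .io import read_series
from .series import TrajectorySet
from .stats import ScaleSummary, summarize_scale, window_stats
from .synthetic import OUComponent, SyntheticModel, simulate
from .windows import TimescaleGrid, extract, plan_windows

log = logging.getLogger("pesrough")

_SUMMARY_COLUMNS = [
    "tau", "m", "n", "window_count", "defined_r_count", "mean_r",
    "mean_sigma_p", "mean_sigma_pw", "mean_sigma_tot", "p_rough", "p_smooth",
    "pct_I", "pct_III", "pct_IV",
]


@dataclass
class InputSpec:
    """Where the trajectories come from: files on disk or a synthetic model."""

    paths: list[str] = field(default_factory=list)
    dialect: str = "plain3col"
    sampling_interval: float = 1.0
    p_columns: list[str] | None = None
    pw_columns: list[str] | None = None
    synthetic: list[SyntheticModel] | None = None


@dataclass
class AnalysisConfig:
    """Full description of one analysis run."""

    input: InputSpec
    scales: TimescaleGrid
    exponents: tuple[int, ...] = (5, 6)
    max_windows: int = 1000
    hist_bins: int = 50
    placement: str = "even"
    seed: int = 0
    output_dir: str = "results/analysis"
    make_plots: bool = False

    def validate(self) -> None:
        problems = []
        if not self.exponents:
            problems.append("exponents: need at least one window exponent")
        if any(m < 1 for m in self.exponents):
            problems.append("exponents: each m must be >= 1")
        if self.max_windows < 1:
            problems.append("max_windows: must be >= 1")
        if self.hist_bins < 1:
            problems.append("hist_bins: must be >= 1")
        if self.placement not in ("even", "random"):
            problems.append(f"placement: unknown mode {self.placement!r}")
        if not self.input.paths and not self.input.synthetic:
            problems.append("input: needs file paths or a synthetic block")
        if problems:
            raise ValidationError("; ".join(problems))


@dataclass
class AnalysisReport:
    """In-memory result of one run: scale summaries per exponent."""

    config: AnalysisConfig
    summaries: dict[int, list[ScaleSummary]]
    skipped_scales: dict[int, list[float]]
    output_dir: Path


def _fmt(x: float) -> str:
    return f"{x:.12g}"


def load_trajectories(cfg: AnalysisConfig) -> TrajectorySet:
    if cfg.input.synthetic:
        return TrajectorySet([simulate(m) for m in cfg.input.synthetic])
    series = [
        read_series(
            p,
            cfg.input.sampling_interval,
            cfg.input.dialect,
            p_columns=cfg.input.p_columns,
            pw_columns=cfg.input.pw_columns,
        )
        for p in cfg.input.paths
    ]
    return TrajectorySet(series)


def analyze_scale(
    trajectories: TrajectorySet,
    tau: float,
    m: int,
    max_windows: int,
    hist_bins: int,
    placement: str = "even",
    seed: int = 0,
):
    """All per-window stats plus their per-scale aggregate at one (tau, m)."""
    plans = plan_windows(trajectories, tau, m, max_windows, placement, seed)
    by_id = {s.trajectory_id: s for s in trajectories}
    stats = [window_stats(*extract(by_id[w.trajectory_id], w)) for w in plans]
    return plans, stats, summarize_scale(stats, tau, m, hist_bins)


def run(cfg: AnalysisConfig) -> AnalysisReport:
    """Execute the full analysis described by ``cfg`` and write its outputs."""
    cfg.validate()
    trajectories = load_trajectories(cfg)
    out_root = Path(cfg.output_dir)
    out_root.mkdir(parents=True, exist_ok=True)

    summaries: dict[int, list[ScaleSummary]] = {}
    skipped: dict[int, list[float]] = {}
    for m in cfg.exponents:
        m_dir = out_root / f"m{m}"
        m_dir.mkdir(parents=True, exist_ok=True)
        rows: list[ScaleSummary] = []
        skipped[m] = []
        hist_doc: dict[str, dict] = {}
        for tau in cfg.scales.scales:
            try:
                plans, stats, summary = analyze_scale(
                    trajectories, tau, m, cfg.max_windows, cfg.hist_bins,
                    cfg.placement, cfg.seed,
                )
            except CapacityError as exc:
                log.warning("skipping scale tau=%s at m=%s: %s", tau, m, exc)
                skipped[m].append(tau)
                continue
            log.info(
                "tau=%s m=%s: %d windows (%d with defined r)",
                tau, m, summary.window_count, summary.defined_r_count,
            )
            rows.append(summary)
            hist_doc[_fmt(tau)] = {
                k: h.as_dict() for k, h in summary.histograms.items()
            }
            _write_windows_tsv(m_dir / f"windows_{_fmt(tau)}.tsv", plans, stats)
        if not rows:
            raise CapacityError(
                f"no scale of the grid is feasible at m={m} for these trajectories"
            )
        summaries[m] = rows
        _write_summary_tsv(m_dir / "summary.tsv", rows)
        with open(m_dir / "histograms.json", "w") as fh:
            json.dump(hist_doc, fh, indent=1, sort_keys=True)

    _write_manifest(out_root, cfg, summaries, skipped)
    if cfg.make_plots:
        from .plotting import plot_report  # matplotlib import deferred

        plot_report(AnalysisReport(cfg, summaries, skipped, out_root))
    return AnalysisReport(cfg, summaries, skipped, out_root)


def _write_summary_tsv(path: Path, rows: list[ScaleSummary]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_SUMMARY_COLUMNS) + "\n")
        for s in rows:
            q = s.quadrant_percentages
            vals = [
                _fmt(s.tau), str(s.m), str(s.n), str(s.window_count),
                str(s.defined_r_count), _fmt(s.mean_r), _fmt(s.mean_sigma_p),
                _fmt(s.mean_sigma_pw), _fmt(s.mean_sigma_tot), _fmt(s.p_rough),
                _fmt(s.p_smooth), _fmt(q["I"]), _fmt(q["III"]), _fmt(q["IV"]),
            ]
            fh.write("\t".join(vals) + "\n")


def _write_windows_tsv(path: Path, plans, stats) -> None:
    with open(path, "w") as fh:
        fh.write(
            "trajectory_id\tstart_index\tstride\tn\t"
            "r\tsigma_p\tsigma_pw\tsigma_tot\tdelta_sigma\tquadrant\n"
        )
        for w, st in zip(plans, stats):
            r_txt = _fmt(st.r) if st.r is not None else "NA"
            fh.write(
                f"{w.trajectory_id}\t{w.start_index}\t{w.stride}\t{w.n}\t"
                f"{r_txt}\t{_fmt(st.sigma_p)}\t{_fmt(st.sigma_pw)}\t"
                f"{_fmt(st.sigma_tot)}\t{_fmt(st.delta_sigma)}\t"
                f"{st.quadrant.value}\n"
            )


def _config_fingerprint(cfg: AnalysisConfig) -> str:
    doc = {
        "paths": list(cfg.input.paths),
        "dialect": cfg.input.dialect,
        "delta": cfg.input.sampling_interval,
        "synthetic": [
            {
                "components": [
                    [c.relaxation_time, c.amplitude_p, c.amplitude_w,
                     c.cross_correlation]
                    for c in m.components
                ],
                "baselines": [m.baseline_p, m.baseline_w],
                "delta": m.sampling_interval,
                "n_steps": m.n_steps,
                "seed": m.seed,
            }
            for m in (cfg.input.synthetic or [])
        ],
        "scales": list(cfg.scales.scales),
        "exponents": list(cfg.exponents),
        "max_windows": cfg.max_windows,
        "hist_bins": cfg.hist_bins,
        "placement": cfg.placement,
        "seed": cfg.seed,
    }
    blob = json.dumps(doc, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def _write_manifest(out_root: Path, cfg, summaries, skipped) -> None:
    import numpy
    import scipy

    from . import __version__

    manifest = {
        "config_sha256": _config_fingerprint(cfg),
        "seed": cfg.seed,
        "exponents": list(cfg.exponents),
        "scales_analysed": {
            str(m): [_fmt(s.tau) for s in rows] for m, rows in summaries.items()
        },
        "scales_skipped": {str(m): [_fmt(t) for t in v] for m, v in skipped.items()},
        "versions": {
            "pesrough": __version__,
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
        },
    }
    with open(out_root / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)


def compare_exponents(reports: list[AnalysisReport], path=None) -> str:
    """Side-by-side mean_r(tau) and mean sigma(tau) across window exponents.

    All reports must cover the same scale grid.  Returns (and optionally
    writes) a TSV with one row per scale and a max-absolute-discrepancy
    column per statistic — the robustness check that conclusions do not
    depend on the window exponent.
    """
    pairs: list[tuple[int, list[ScaleSummary]]] = []
    for rep in reports:
        for m, rows in sorted(rep.summaries.items()):
            pairs.append((m, rows))
    if len(pairs) < 2:
        raise ValidationError("compare_exponents needs at least two exponents")
    grids = [tuple(s.tau for s in rows) for _, rows in pairs]
    if len(set(grids)) != 1:
        raise ValidationError(f"scale grids differ across reports: {sorted(set(grids))}")

    ms = [m for m, _ in pairs]
    if len(set(ms)) != len(ms):
        raise ValidationError(f"duplicate exponents across reports: {ms}")
    header = ["tau"]
    for m in ms:
        header += [f"mean_r_m{m}", f"mean_sigma_tot_m{m}"]
    header += ["max_abs_dr", "max_abs_dsigma_tot"]
    lines = ["\t".join(header)]
    for i, tau in enumerate(grids[0]):
        rs = [rows[i].mean_r for _, rows in pairs]
        sigs = [rows[i].mean_sigma_tot for _, rows in pairs]
        row = [_fmt(tau)]
        for r, s in zip(rs, sigs):
            row += [_fmt(r), _fmt(s)]
        row += [_fmt(max(rs) - min(rs)), _fmt(max(sigs) - min(sigs))]
        lines.append("\t".join(row))
    text = "\n".join(lines) + "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


# ---------------------------------------------------------------------------
# YAML config loading

def config_from_dict(doc: dict) -> AnalysisConfig:
    """Build an AnalysisConfig from a plain dict (parsed YAML)."""
    try:
        inp = doc["input"]
        delta = float(inp.get("sampling_interval", 1.0))
        synthetic = None
        if "synthetic" in inp:
            synthetic = []
            for blk in inp["synthetic"]:
                comps = tuple(
                    OUComponent(
                        relaxation_time=float(c["relaxation_time"]),
                        amplitude_p=float(c["amplitude_p"]),
                        amplitude_w=float(c["amplitude_w"]),
                        cross_correlation=float(c.get("cross_correlation", 0.0)),
                    )
                    for c in blk["components"]
                )
                synthetic.append(
                    SyntheticModel(
                        components=comps,
                        baseline_p=float(blk.get("baseline_p", 0.0)),
                        baseline_w=float(blk.get("baseline_w", 0.0)),
                        sampling_interval=delta,
                        n_steps=int(blk["n_steps"]),
                        seed=int(blk.get("seed", 0)),
                    )
                )
        input_spec = InputSpec(
            paths=list(inp.get("paths", [])),
            dialect=inp.get("dialect", "plain3col"),
            sampling_interval=delta,
            p_columns=inp.get("p_columns"),
            pw_columns=inp.get("pw_columns"),
            synthetic=synthetic,
        )
        grid = TimescaleGrid(tuple(float(s) for s in doc["scales"]), delta)
        return AnalysisConfig(
            input=input_spec,
            scales=grid,
            exponents=tuple(int(m) for m in doc.get("exponents", [5, 6])),
            max_windows=int(doc.get("max_windows", 1000)),
            hist_bins=int(doc.get("hist_bins", 50)),
            placement=doc.get("placement", "even"),
            seed=int(doc.get("seed", 0)),
            output_dir=doc.get("output_dir", "results/analysis"),
            make_plots=bool(doc.get("make_plots", False)),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ValidationError(f"malformed config: {exc!r}") from exc


def load_config(path) -> AnalysisConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ValidationError("config file must hold a mapping")
    return config_from_dict(doc)
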