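"""Advisory figures for an analysis report.

Four panels mirror the standard presentation of the analysis: the mean
correlation r as a function of time scale; r distributions at selected
scales; mean sigmas versus time scale together with the smoothing /
roughening probabilities; and per-scale (Delta_sigma, r) quadrant scatters.
Figures are illustrative output only — the TSV/JSON tables are the tested
surface.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np


def _log_tau(taus, delta):
    return np.log10(np.asarray(taus) / delta)


def plot_report(report) -> list[Path]:
    written = []
    for m, rows in sorted(report.summaries.items()):
        out = report.output_dir / f"m{m}"
        taus = [s.tau for s in rows]
        x = _log_tau(taus, report.config.scales.base_interval)

        fig, axes = plt.subplots(2, 2, figsize=(10, 8))
        ax = axes[0, 0]
        ax.plot(x, [s.mean_r for s in rows], "o-")
        ax.axhline(0.0, color="grey", lw=0.5)
        ax.set_xlabel("log10(tau / delta)")
        ax.set_ylabel("mean r")
        ax.set_title("E_p vs E_p-w correlation by time scale")

        ax = axes[0, 1]
        for s in rows:
            h = s.histograms["r"]
            if h.counts.size:
                centers = 0.5 * (h.bin_edges[:-1] + h.bin_edges[1:])
                ax.plot(centers, h.counts / h.counts.sum(),
                        label=f"tau/delta={s.tau / report.config.scales.base_interval:g}")
        ax.set_xlabel("r")
        ax.set_ylabel("probability")
        ax.legend(fontsize=6)
        ax.set_title("r distributions")

        ax = axes[1, 0]
        for key, lab in (("mean_sigma_p", "sigma_p"),
                         ("mean_sigma_pw", "sigma_p-w"),
                         ("mean_sigma_tot", "sigma_tot")):
            ax.plot(x, [getattr(s, key) for s in rows], "o-", label=lab)
        ax.set_xlabel("log10(tau / delta)")
        ax.set_ylabel("mean sigma (kcal/mol)")
        ax.legend()
        ax.set_title("roughness by time scale")

        ax = axes[1, 1]
        ax.plot(x, [s.p_rough for s in rows], "o-", label="P(sigma_tot >= sigma_p)")
        ax.plot(x, [s.p_smooth for s in rows], "s-", label="P(sigma_tot < sigma_p)")
        ax.set_xlabel("log10(tau / delta)")
        ax.set_ylabel("probability")
        ax.legend()
        ax.set_title("roughening vs smoothing")

        fig.tight_layout()
        path = out / "overview.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)

        written.extend(_quadrant_scatters(out, rows, report))
    return written


def _quadrant_scatters(out: Path, rows, report):
    import csv

    written = []
    for s in rows:
        tsv = out / f"windows_{s.tau:.12g}.tsv"
        if not tsv.exists():
            continue
        ds, rv = [], []
        with open(tsv) as fh:
            for rec in csv.DictReader(fh, delimiter="\t"):
                if rec["r"] == "NA":
                    continue
                ds.append(float(rec["delta_sigma"]))
                rv.append(float(rec["r"]))
        if not ds:
            continue
        fig, ax = plt.subplots(figsize=(5, 5))
        ax.scatter(ds, rv, s=4, alpha=0.4)
        ax.axhline(0, color="grey", lw=0.5)
        ax.axvline(0, color="grey", lw=0.5)
        ax.set_xlabel("delta_sigma = sigma_tot - sigma_p (kcal/mol)")
        ax.set_ylabel("r")
        ax.set_title(f"quadrants, tau/delta="
                     f"{s.tau / report.config.scales.base_interval:g}, m={s.m}")
        path = out / f"quadrants_{s.tau:.12g}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    return written
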