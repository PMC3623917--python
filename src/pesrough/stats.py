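"""Per-window and per-scale roughness statistics.

For each window the analysis computes the Pearson correlation r between the
protein self energy E_p and the protein-water interaction energy E_p-w, the
population standard deviations sigma_p, sigma_pw and sigma_tot (of
E_tot = E_p + E_p-w), and the roughness change Delta_sigma = sigma_tot -
sigma_p.  The sample identity

    sigma_tot^2 = sigma_p^2 + sigma_pw^2 + 2 r sigma_p sigma_pw

holds exactly in population form and is asserted on every window.

Windows are classified on the (x = Delta_sigma, y = r) plane:

    I   : Delta_sigma > 0, r > 0   — water roughens, energies reinforce
    IV  : Delta_sigma > 0, r <= 0  — water roughens despite compensation
    III : Delta_sigma < 0, r < 0   — water smooths the landscape
    II  : Delta_sigma < 0, r >= 0  — algebraically impossible when
                                     sigma_pw > 0 (from the identity above,
                                     r >= 0 forces sigma_tot > sigma_p)

Delta_sigma = 0 counts as roughening (ties go with "larger than or equal
to").  Only this axis orientation makes quadrant II the impossible region
while leaving the common slaving case (r < 0 yet Delta_sigma > 0) in
quadrant IV.

All moments are population form (divide by n), matching the common
sqrt(<E^2> - <E>^2) definition; computed two-pass (centred) for numerical
stability against the large baseline offsets of MD energies.  A
divide-by-(n-1) option exists but is off by default.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .errors import SizeError

#: Relative tolerance for the per-window variance-decomposition identity.
IDENTITY_RTOL = 1e-9


class Quadrant(enum.Enum):
    I = "I"
    II = "II"
    III = "III"
    IV = "IV"
    UNDEFINED = "undefined"


class QuadrantIIError(AssertionError):
    """A window landed in the impossible quadrant (r >= 0 but sigma_tot < sigma_p)."""


def _moments(x: np.ndarray, ddof: int = 0) -> tuple[float, float]:
    if x.ndim != 1 or len(x) < 2:
        raise SizeError("window must be 1-D with n >= 2")
    mean = float(x.mean())
    var = float(np.mean((x - mean) ** 2))
    if ddof:
        var *= len(x) / (len(x) - ddof)
    return mean, max(var, 0.0)


def sigma(x: np.ndarray, ddof: int = 0) -> float:
    """Population standard deviation sqrt(<x^2> - <x>^2), clipped at 0."""
    _, var = _moments(np.asarray(x, dtype=np.float64), ddof)
    return float(np.sqrt(var))


def pearson_r(x: np.ndarray, y: np.ndarray) -> float | None:
    """Pearson product-moment correlation of two equal-length windows.

    Population-form moments (means over the n window points).  Returns
    ``None`` — an explicit undefined flag, not NaN — if either window has
    zero variance.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if len(x) != len(y):
        raise SizeError(f"window lengths differ: {len(x)} != {len(y)}")
    mx, vx = _moments(x)
    my, vy = _moments(y)
    if vx == 0.0 or vy == 0.0:
        return None
    cov = float(np.mean((x - mx) * (y - my)))
    r = cov / np.sqrt(vx * vy)
    return float(min(1.0, max(-1.0, r)))


@dataclass(frozen=True)
class WindowStats:
    """Statistics of one window (all sigmas in kcal/mol)."""

    r: float | None
    sigma_p: float
    sigma_pw: float
    sigma_tot: float
    quadrant: Quadrant

    @property
    def delta_sigma(self) -> float:
        return self.sigma_tot - self.sigma_p

    @property
    def smoothing(self) -> bool:
        """True when water smooths the local landscape (sigma_tot < sigma_p)."""
        return self.sigma_tot < self.sigma_p


def _classify(delta_sigma: float, r: float | None, sigma_pw: float) -> Quadrant:
    if r is None:
        return Quadrant.UNDEFINED
    if delta_sigma >= 0:  # ties count as roughening
        return Quadrant.I if r > 0 else Quadrant.IV
    if r < 0:
        return Quadrant.III
    if sigma_pw > 0:
        raise QuadrantIIError(
            f"impossible window: r={r} >= 0 yet delta_sigma={delta_sigma} < 0 "
            f"with sigma_pw={sigma_pw} > 0"
        )
    return Quadrant.II


def window_stats(e_p: np.ndarray, e_pw: np.ndarray, ddof: int = 0) -> WindowStats:
    """Compute all per-window statistics and verify the variance identity.

    Raises :class:`QuadrantIIError` if round-off ever produces a window in
    the impossible region (r >= 0 with sigma_tot < sigma_p and sigma_pw > 0)
    — by design the run fails loudly rather than silently reclassifying.
    """
    e_p = np.asarray(e_p, dtype=np.float64)
    e_pw = np.asarray(e_pw, dtype=np.float64)
    if len(e_p) != len(e_pw):
        raise SizeError(f"window lengths differ: {len(e_p)} != {len(e_pw)}")
    s_p = sigma(e_p, ddof)
    s_pw = sigma(e_pw, ddof)
    s_tot = sigma(e_p + e_pw, ddof)
    r = pearson_r(e_p, e_pw)
    if r is not None:
        lhs = s_tot**2
        rhs = s_p**2 + s_pw**2 + 2.0 * r * s_p * s_pw
        if abs(lhs - rhs) > IDENTITY_RTOL * max(1.0, lhs):
            raise AssertionError(
                f"variance-decomposition identity violated: {lhs} vs {rhs}"
            )
    return WindowStats(r, s_p, s_pw, s_tot, _classify(s_tot - s_p, r, s_pw))


@dataclass(frozen=True)
class Histogram:
    """Equal-width histogram (right edge inclusive in the last bin)."""

    bin_edges: np.ndarray
    counts: np.ndarray

    def as_dict(self) -> dict:
        return {
            "bin_edges": [float(e) for e in self.bin_edges],
            "counts": [int(c) for c in self.counts],
        }


def _hist(values: np.ndarray, bins: int) -> Histogram:
    if values.size == 0:
        return Histogram(np.zeros(0), np.zeros(0, dtype=np.int64))
    lo, hi = float(values.min()), float(values.max())
    if hi - lo <= max(abs(lo), abs(hi), 1.0) * 1e-12:
        # numerically single-valued: centre a unit-wide range on the value
        lo, hi = lo - 0.5, lo + 0.5
    counts, edges = np.histogram(values, bins=bins, range=(lo, hi))
    return Histogram(edges, counts)


@dataclass(frozen=True)
class ScaleSummary:
    """Aggregates over all windows at one time scale."""

    tau: float
    m: int
    window_count: int
    defined_r_count: int
    mean_r: float
    mean_sigma_p: float
    mean_sigma_pw: float
    mean_sigma_tot: float
    p_rough: float
    p_smooth: float
    quadrant_percentages: dict[str, float]
    histograms: dict[str, Histogram]

    @property
    def n(self) -> int:
        return 2**self.m


def summarize_scale(
    stats: list[WindowStats], tau: float, m: int, hist_bins: int = 50
) -> ScaleSummary:
    """Aggregate per-window statistics at one scale.

    mean_r and the quadrant percentages run over defined-r windows only;
    the sigma means and the smoothing/roughening probabilities run over all
    windows (both remain well defined when r is not).  p_smooth uses the
    strict inequality sigma_tot < sigma_p; ties count as roughening.
    """
    if not stats:
        raise SizeError("summarize_scale needs at least one window")
    n_all = len(stats)
    r_vals = np.array([w.r for w in stats if w.r is not None], dtype=np.float64)
    sig_p = np.array([w.sigma_p for w in stats])
    sig_pw = np.array([w.sigma_pw for w in stats])
    sig_tot = np.array([w.sigma_tot for w in stats])
    n_smooth = sum(1 for w in stats if w.smoothing)

    quad_counts = {q: 0 for q in ("I", "III", "IV")}
    for w in stats:
        if w.quadrant in (Quadrant.I, Quadrant.III, Quadrant.IV):
            quad_counts[w.quadrant.value] += 1
    n_def = len(r_vals)
    quad_pct = {
        q: (100.0 * c / n_def if n_def else float("nan"))
        for q, c in quad_counts.items()
    }

    return ScaleSummary(
        tau=tau,
        m=m,
        window_count=n_all,
        defined_r_count=n_def,
        mean_r=float(r_vals.mean()) if n_def else float("nan"),
        mean_sigma_p=float(sig_p.mean()),
        mean_sigma_pw=float(sig_pw.mean()),
        mean_sigma_tot=float(sig_tot.mean()),
        p_rough=1.0 - n_smooth / n_all,
        p_smooth=n_smooth / n_all,
        quadrant_percentages=quad_pct,
        histograms={
            "r": _hist(r_vals, hist_bins),
            "sigma_p": _hist(sig_p, hist_bins),
            "sigma_pw": _hist(sig_pw, hist_bins),
            "sigma_tot": _hist(sig_tot, hist_bins),
        },
    )
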