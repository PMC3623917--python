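"""Reading and writing energy time series.

Three dialects are supported:

``plain2col``
    Whitespace- or comma-separated columns ``E_p  E_p-w``, one frame per
    line; lines starting with ``#`` are comments.
``plain3col``
    Columns ``time  E_p  E_p-w``.  The time column is validated as a uniform
    grid against the declared sampling interval (max deviation < 1e-6*delta)
    and then discarded.  This is also the write format; round trips are
    bit-exact.
``namd_log``
    NAMD-style log files: a single ``ETITLE:`` header naming the energy
    columns, then one ``ENERGY:`` line per frame.  The caller declares which
    named columns sum to E_p and which to E_p-w (the force-field
    decomposition is deliberately left to the user).
"""

from __future__ import annotations

import os
from collections.abc import Sequence

import numpy as np

from .errors import FormatError
from .series import EnergySeries

DIALECTS = ("plain2col", "plain3col", "namd_log")


def _split_fields(line: str) -> list[str]:
    return line.replace(",", " ").split()


def _parse_plain(path, lines, n_cols: int):
    rows = []
    for lineno, raw in lines:
        fields = _split_fields(raw)
        if len(fields) != n_cols:
            raise FormatError(
                f"expected {n_cols} columns, got {len(fields)}", path, lineno
            )
        try:
            rows.append([float(f) for f in fields])
        except ValueError:
            raise FormatError("non-numeric field", path, lineno) from None
    return np.asarray(rows, dtype=np.float64)


def read_series(
    path,
    sampling_interval: float,
    dialect: str = "plain2col",
    trajectory_id: str | None = None,
    p_columns: Sequence[str] | None = None,
    pw_columns: Sequence[str] | None = None,
) -> EnergySeries:
    """Read one trajectory's (E_p, E_p-w) series from a text file.

    Parameters
    ----------
    path:
        File to read.
    sampling_interval:
        Grid spacing delta of the stored frames.
    dialect:
        One of ``plain2col``, ``plain3col``, ``namd_log``.
    p_columns, pw_columns:
        For ``namd_log`` only: names of ETITLE columns summed per frame to
        form E_p and E_p-w respectively.

    Raises
    ------
    FormatError
        On ragged rows, non-numeric fields, a non-uniform time grid, an
        ETITLE/ENERGY column-count mismatch, or an empty series; the error
        names the offending line.
    """
    if dialect not in DIALECTS:
        raise FormatError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    tid = trajectory_id if trajectory_id is not None else os.path.basename(str(path))

    with open(path) as fh:
        raw_lines = fh.readlines()

    if dialect == "namd_log":
        return _read_namd_log(path, raw_lines, sampling_interval, tid, p_columns, pw_columns)

    data_lines = [
        (i + 1, ln)
        for i, ln in enumerate(raw_lines)
        if ln.strip() and not ln.lstrip().startswith("#")
    ]
    if not data_lines:
        raise FormatError("empty series", path)

    if dialect == "plain2col":
        arr = _parse_plain(path, data_lines, 2)
        e_p, e_pw = arr[:, 0], arr[:, 1]
    else:  # plain3col
        arr = _parse_plain(path, data_lines, 3)
        t, e_p, e_pw = arr[:, 0], arr[:, 1], arr[:, 2]
        if len(t) >= 2:
            expected = t[0] + np.arange(len(t)) * sampling_interval
            dev = np.abs(t - expected)
            bad = np.nonzero(dev >= 1e-6 * sampling_interval)[0]
            if bad.size:
                raise FormatError(
                    "non-uniform time grid "
                    f"(deviation {dev[bad[0]]:g} at frame {bad[0]})",
                    path,
                    data_lines[bad[0]][0],
                )

    return EnergySeries(tid, sampling_interval, e_p, e_pw)


def _read_namd_log(path, raw_lines, delta, tid, p_columns, pw_columns):
    if not p_columns or not pw_columns:
        raise FormatError(
            "namd_log dialect requires p_columns and pw_columns", path
        )
    header: list[str] | None = None
    e_p_vals: list[float] = []
    e_pw_vals: list[float] = []
    p_idx: list[int] = []
    pw_idx: list[int] = []
    n_data = 0
    for lineno, raw in enumerate(raw_lines, start=1):
        if raw.startswith("ETITLE:"):
            if header is None:
                header = raw.split()[1:]
                for name in list(p_columns) + list(pw_columns):
                    if name not in header:
                        raise FormatError(
                            f"column {name!r} not in ETITLE header", path, lineno
                        )
                p_idx = [header.index(c) for c in p_columns]
                pw_idx = [header.index(c) for c in pw_columns]
            continue
        if not raw.startswith("ENERGY:"):
            continue
        if header is None:
            raise FormatError("ENERGY: line before any ETITLE: header", path, lineno)
        fields = raw.split()[1:]
        if len(fields) != len(header):
            raise FormatError(
                f"ENERGY line has {len(fields)} fields, ETITLE names {len(header)}",
                path,
                lineno,
            )
        try:
            vals = [float(f) for f in fields]
        except ValueError:
            raise FormatError("non-numeric field in ENERGY line", path, lineno) from None
        e_p_vals.append(sum(vals[i] for i in p_idx))
        e_pw_vals.append(sum(vals[i] for i in pw_idx))
        n_data += 1
    if n_data == 0:
        raise FormatError("empty series", path)
    return EnergySeries(tid, delta, np.asarray(e_p_vals), np.asarray(e_pw_vals))


def write_series(series: EnergySeries, path) -> None:
    """Write a series as plain3col text at full float precision.

    ``read_series(write_series(s))`` reproduces ``s`` bit-for-bit: floats are
    printed with %.17g, enough digits to round-trip any IEEE double.
    """
    try:
        with open(path, "w") as fh:
            fh.write(
                f"# trajectory_id={series.trajectory_id} "
                f"delta={series.sampling_interval:.17g} n={len(series)}\n"
            )
            fh.write("# time e_p e_pw\n")
            for t, p, w in zip(series.times, series.e_p, series.e_pw):
                fh.write(f"{t:.17g} {p:.17g} {w:.17g}\n")
    except OSError as exc:
        raise OSError(f"cannot write series to {path}: {exc}") from exc
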