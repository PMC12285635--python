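"""Batch scoring and metric-correlation analysis.

``batch_evaluate`` scores a corpus of (generated, reference) pairs with
every metric, isolating per-image failures in the report's ``flags``.
``metric_correlations`` computes the pairwise Pearson correlation matrix
over the corpus, with two-sided t-test p-values at n - 2 degrees of
freedom.  The naturalness factor enters the correlations as its
deviation from the target, ``1 - N_f``, because N_f itself is not
monotone in quality (both N_f >> 1 and N_f << 1 are bad).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidInputError, NatFactorError
from .gradients import NaturalnessPrior, naturalness_factor
from .image import as_gray_image
from .metrics import MetricReport, decorrelation_curve, mae, ms_ssim, psnr, rms_contrast

#: Column order of the correlation analysis.
METRIC_COLUMNS = ("ms_ssim", "mae", "psnr", "contrast", "resolution_nm", "one_minus_nf")


def _unit(a: np.ndarray) -> np.ndarray:
    lo, hi = a.min(), a.max()
    return np.zeros_like(a) if hi == lo else (a - lo) / (hi - lo)


@dataclass(frozen=True)
class CorrelationCell:
    """One entry of the pairwise metric-correlation matrix."""

    metric_a: str
    metric_b: str
    r: float
    r_squared: float
    p_value: float
    n: int
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not self.degenerate:
            if abs(self.r) > 1 + 1e-12:
                raise InvalidInputError("r must lie in [-1, 1]")
            if abs(self.r_squared - self.r**2) > 1e-12:
                raise InvalidInputError("r_squared must equal r**2")
            if not 0.0 <= self.p_value <= 1.0:
                raise InvalidInputError("p_value must lie in [0, 1]")


def batch_evaluate(
    pairs: Sequence[tuple],
    prior: NaturalnessPrior | None = None,
    theta: float = 0.5,
    mae_scale: str | None = "unit",
) -> list[MetricReport]:
    """Score every (generated, reference) pair with the full metric suite.

    A metric that cannot be computed for one pair (degenerate image,
    missing pixel size, too small for MS-SSIM, ...) is recorded in that
    report's ``flags`` instead of aborting the batch.

    When ``mae_scale`` requests normalized comparison (the default),
    PSNR is likewise computed on the min-max-normalized pair; PSNR is
    invariant to the particular normalization scale, and normalizing
    removes the dependence on absolute photon counts when corpora mix
    acquisition intensities.
    """
    pairs = list(pairs)
    if not pairs:
        raise InvalidInputError("empty corpus")
    reports = []
    for gen, ref in pairs:
        gen = as_gray_image(gen)
        ref = as_gray_image(ref)
        values: dict = {}
        flags: set[str] = set()

        def attempt(name, fn):
            try:
                values[name] = fn()
            except NatFactorError:
                flags.add(name)

        attempt("mae", lambda: mae(gen, ref, scale=mae_scale))
        if mae_scale is None:
            attempt("psnr", lambda: psnr(gen, ref))
        else:
            attempt(
                "psnr",
                lambda: psnr(
                    _unit(gen.pixels), _unit(ref.pixels), max_intensity=1.0
                ),
            )
        attempt("ms_ssim", lambda: ms_ssim(gen, ref))
        attempt("contrast", lambda: rms_contrast(gen))
        attempt("resolution_nm", lambda: decorrelation_curve(gen).resolution_nm)
        attempt("nf", lambda: naturalness_factor(gen, prior=prior, theta=theta).nf)
        reports.append(MetricReport(flags=frozenset(flags), **values))
    return reports


def _columns(reports: Sequence[MetricReport]) -> pd.DataFrame:
    rows = []
    for rep in reports:
        rows.append(
            {
                "ms_ssim": rep.ms_ssim,
                "mae": rep.mae,
                "psnr": rep.psnr,
                "contrast": rep.contrast,
                "resolution_nm": rep.resolution_nm,
                "one_minus_nf": None if rep.nf is None else 1.0 - rep.nf,
            }
        )
    return pd.DataFrame(rows, columns=list(METRIC_COLUMNS), dtype=float)


def metric_correlations(reports: Sequence[MetricReport]) -> list[CorrelationCell]:
    """Pairwise Pearson correlations over all unordered metric pairs.

    Incomplete reports are dropped pairwise-complete per metric pair, and
    the per-cell n (hence the n - 2 t-test degrees of freedom) reflects
    that.  A metric with zero variance across the corpus yields
    degenerate cells with NaN statistics.
    """
    if len(reports) < 4:
        raise InvalidInputError("need at least 4 reports for correlations")
    df = _columns(reports)
    cells = []
    for a, b in combinations(METRIC_COLUMNS, 2):
        mask = df[a].notna() & df[b].notna()
        x = df.loc[mask, a].to_numpy()
        y = df.loc[mask, b].to_numpy()
        n = int(mask.sum())
        if n < 4 or np.std(x) == 0 or np.std(y) == 0:
            cells.append(
                CorrelationCell(a, b, np.nan, np.nan, np.nan, n, degenerate=True)
            )
            continue
        r, p = stats.pearsonr(x, y)
        cells.append(
            CorrelationCell(
                metric_a=a,
                metric_b=b,
                r=float(r),
                r_squared=float(r) ** 2,
                p_value=float(p),
                n=n,
            )
        )
    return cells


def correlation_matrix(cells: Sequence[CorrelationCell]) -> pd.DataFrame:
    """Symmetric correlation matrix (unit diagonal) from the cell list."""
    names = sorted({c.metric_a for c in cells} | {c.metric_b for c in cells})
    mat = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for c in cells:
        mat.loc[c.metric_a, c.metric_b] = c.r
        mat.loc[c.metric_b, c.metric_a] = c.r
    return mat


# ---------------------------------------------------------------------------
# reporting


def _reports_frame(reports: Sequence[MetricReport]) -> pd.DataFrame:
    rows = []
    for rep in reports:
        row = {
            name: getattr(rep, name)
            for name in ("mae", "psnr", "ms_ssim", "contrast", "resolution_nm", "nf")
        }
        row["flags"] = ";".join(sorted(rep.flags))
        rows.append(row)
    return pd.DataFrame(rows)


def write_report(
    cells: Sequence[CorrelationCell],
    reports: Sequence[MetricReport],
    path,
) -> None:
    """Write ``reports.csv``, ``correlations.csv`` and ``correlations.json``.

    ``path`` is a directory (created if needed).  Floats are written with
    17 significant digits so the CSV round-trips losslessly.
    """
    out = Path(path)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:  # unwritable location
        raise InvalidInputError(f"cannot create output directory {out}: {exc}")
    _reports_frame(reports).to_csv(out / "reports.csv", index=False, float_format="%.17g")
    cell_rows = [
        {
            "metric_a": c.metric_a,
            "metric_b": c.metric_b,
            "r": c.r,
            "r_squared": c.r_squared,
            "p_value": c.p_value,
            "n": c.n,
            "degenerate": c.degenerate,
        }
        for c in cells
    ]
    pd.DataFrame(
        cell_rows,
        columns=["metric_a", "metric_b", "r", "r_squared", "p_value", "n", "degenerate"],
    ).to_csv(out / "correlations.csv", index=False, float_format="%.17g")
    with open(out / "correlations.json", "w") as fh:
        json.dump({"correlations": cell_rows}, fh, indent=2, default=float)


def read_report(path) -> tuple[list[CorrelationCell], list[MetricReport]]:
    """Read back what :func:`write_report` wrote."""
    out = Path(path)
    cells = []
    cdf = pd.read_csv(out / "correlations.csv")
    for _, row in cdf.iterrows():
        cells.append(
            CorrelationCell(
                metric_a=row["metric_a"],
                metric_b=row["metric_b"],
                r=float(row["r"]),
                r_squared=float(row["r_squared"]),
                p_value=float(row["p_value"]),
                n=int(row["n"]),
                degenerate=bool(row["degenerate"]),
            )
        )
    reports = []
    rdf = pd.read_csv(out / "reports.csv")
    for _, row in rdf.iterrows():
        kwargs = {}
        for name in ("mae", "psnr", "ms_ssim", "contrast", "resolution_nm", "nf"):
            v = row[name]
            kwargs[name] = None if pd.isna(v) else float(v)
        flags = row.get("flags")
        flag_set = frozenset() if pd.isna(flags) or not flags else frozenset(str(flags).split(";"))
        reports.append(MetricReport(flags=flag_set, **kwargs))
    return cells, reports
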