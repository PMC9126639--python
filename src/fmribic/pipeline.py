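"""Comparison methodology over pooled bicluster metrics.

Given per-bicluster quality records this module produces the study-level
artefacts: median +/- sd summary tables per algorithm, bicluster size
summaries, top-K selection with a virtual-error floor, pooled
biclustering-vs-clustering comparisons, and pattern-type inference from
the squared Pearson correlation of the virtual error with each
pattern-specific index (variance -> constant, MSR -> shifting,
SMSR -> scaling).

Every operation accepts either a list of :class:`~fmribic.metrics.MetricsRecord`
or an equivalent DataFrame (as produced by
:func:`~fmribic.metrics.records_to_frame` / read back from the metrics CSV).

Conventions: "top" means smallest virtual error; ties prefer larger area.
Summary medians ignore undefined (NaN) SMSR values but count them.  The
sd paired with each median is the sample standard deviation (0 for a
single record).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .metrics import records_to_frame

__all__ = [
    "PatternTypeReport",
    "summarize_metrics",
    "topk_filter",
    "size_summary",
    "infer_pattern_type",
    "compare_groups",
]

_METRICS = ("var", "msr", "smsr", "ve")

#: argmax mapping from best-correlated index to pattern family
_LABELS = {"var": "constant", "msr": "shifting", "smsr": "scaling"}


def _as_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    return records_to_frame(list(records))


def _sd(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1)) if len(x) >= 2 else 0.0


@dataclass(frozen=True)
class PatternTypeReport:
    """Squared Pearson correlations of VE with each index, and the label.

    The label is the family whose index correlates best with VE
    (``undetermined`` when every r^2 is below ``floor`` or fewer than 3
    usable records exist).
    """

    r2_var: float
    r2_msr: float
    r2_smsr: float
    inferred_label: str
    n_records: int


def summarize_metrics(records, by: str = "algorithm") -> pd.DataFrame:
    """Median and sample sd of each quality index per group.

    Returns a tidy frame with columns group, metric, median, sd, n,
    n_undefined; undefined (NaN) SMSR values are excluded from the median
    and counted in n_undefined.  Groups with no records are omitted with a
    warning.
    """
    frame = _as_frame(records)
    rows = []
    for g in sorted(frame[by].astype(str).unique()):
        sub = frame[frame[by].astype(str) == g]
        if sub.empty:
            warnings.warn(f"group {g!r} has no records; omitted")
            continue
        for metric in _METRICS:
            vals = sub[metric].to_numpy(dtype=float)
            defined = vals[np.isfinite(vals)]
            rows.append(
                {
                    "group": g,
                    "metric": metric,
                    "median": float(np.median(defined)) if len(defined) else np.nan,
                    "sd": _sd(defined),
                    "n": int(len(defined)),
                    "n_undefined": int(len(vals) - len(defined)),
                }
            )
    return pd.DataFrame(
        rows, columns=["group", "metric", "median", "sd", "n", "n_undefined"]
    )


def topk_filter(records, k: int, ve_min: float = 0.01):
    """Best-K selection by virtual error.

    Records with VE below ``ve_min`` are removed first (near-zero VE on
    real outputs is typically a statistical artifact of tiny or degenerate
    biclusters), the rest are sorted by ascending VE — ties broken by
    larger area, then input order — and the first ``k`` returned.  The
    return type matches the input (record list in, record list out;
    DataFrame in, DataFrame out).
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    frame = _as_frame(records)
    ve = frame["ve"].to_numpy(dtype=float)
    area = frame["area"].to_numpy(dtype=float)
    keep = [i for i in range(len(frame)) if ve[i] >= ve_min]
    keep.sort(key=lambda i: (ve[i], -area[i], i))
    keep = keep[:k]
    if isinstance(records, pd.DataFrame):
        return records.iloc[keep].reset_index(drop=True)
    return [records[i] for i in keep]


def size_summary(records, by: str = "algorithm") -> pd.DataFrame:
    """Median +/- sample sd of time points, region points and area per group.

    The area median is taken over the area distribution itself, not the
    product of the other two medians.
    """
    frame = _as_frame(records)
    rows = []
    for g in sorted(frame[by].astype(str).unique()):
        sub = frame[frame[by].astype(str) == g]
        if sub.empty:
            continue
        for name, col in (
            ("time_points", "n_cols"),
            ("region_points", "n_rows"),
            ("area", "area"),
        ):
            vals = sub[col].to_numpy(dtype=float)
            rows.append(
                {
                    "group": g,
                    "dimension": name,
                    "median": float(np.median(vals)),
                    "sd": _sd(vals),
                    "n": int(len(sub)),
                }
            )
    return pd.DataFrame(rows, columns=["group", "dimension", "median", "sd", "n"])


def _r_squared(x: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    """Pairwise-complete squared Pearson correlation; 0 for degenerate input."""
    ok = np.isfinite(x) & np.isfinite(y)
    n = int(ok.sum())
    if n < 3:
        return 0.0, n
    xs, ys = x[ok], y[ok]
    if np.std(xs) == 0.0 or np.std(ys) == 0.0:
        return 0.0, n
    r = float(np.corrcoef(xs, ys)[0, 1])
    return r * r, n


def infer_pattern_type(records, floor: float = 0.01) -> PatternTypeReport:
    """Infer the dominant pattern family of a bicluster collection.

    Computes the squared Pearson correlation of VE against VAR, MSR and
    SMSR across records (pairwise-complete, so undefined SMSR values only
    drop their own pairs).  The family whose index tracks VE best is
    reported; when all correlations sit below ``floor`` — or fewer than 3
    usable records exist — the collection is ``undetermined``.
    """
    frame = _as_frame(records)
    ve = frame["ve"].to_numpy(dtype=float) if len(frame) else np.array([])
    r2: dict[str, float] = {}
    usable = 0
    for metric in ("var", "msr", "smsr"):
        vals = frame[metric].to_numpy(dtype=float) if len(frame) else np.array([])
        r2[metric], n_pairs = _r_squared(ve, vals)
        usable = max(usable, n_pairs)
    if usable < 3 or all(v < floor for v in r2.values()):
        label = "undetermined"
    else:
        label = _LABELS[max(r2, key=lambda m: (r2[m], m))]
    return PatternTypeReport(
        r2_var=r2["var"],
        r2_msr=r2["msr"],
        r2_smsr=r2["smsr"],
        inferred_label=label,
        n_records=len(frame),
    )


def compare_groups(
    records, group_map: dict[str, str], metric: str = "ve"
) -> pd.DataFrame:
    """Pool records into super-groups and order them by median index value.

    ``group_map`` maps algorithm names to super-groups (e.g. biclustering /
    region_clustering / temporal_clustering); records from unmapped
    algorithms are ignored.  Returns a frame sorted by ascending median
    (best first) with columns supergroup, metric, median, n.
    """
    if metric not in _METRICS:
        raise ValueError(f"unknown metric {metric!r}")
    frame = _as_frame(records)
    pooled: dict[str, list[float]] = {}
    for alg, val in zip(frame["algorithm"].astype(str), frame[metric]):
        sg = group_map.get(alg)
        if sg is None or not np.isfinite(val):
            continue
        pooled.setdefault(sg, []).append(float(val))
    rows = [
        {
            "supergroup": sg,
            "metric": metric,
            "median": float(np.median(vals)),
            "n": len(vals),
        }
        for sg, vals in pooled.items()
    ]
    out = pd.DataFrame(rows, columns=["supergroup", "metric", "median", "n"])
    return out.sort_values(["median", "supergroup"], kind="mergesort").reset_index(
        drop=True
    )
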