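"""Feature-prevalence bookkeeping and printed-precision percentage formatting.

Tomogram catalogs tally which cellular features (microtubules, vesicles,
synapses, ...) were observed in each tomogram; prevalence is reported as
``(k/n, or p%)``.  Percentages default to the nearest integer, switching to
one decimal below 1% (or when the caller requests a precision), with the raw
k/n always carried alongside so rounding loses nothing.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable

import pandas as pd

__all__ = [
    "PrevalenceResult",
    "UnknownFeatureError",
    "format_percent",
    "ratio_report",
    "prevalence",
    "prevalence_table",
    "load_catalog",
    "prevalence_phrase",
]

CATALOG_COLUMNS = ("tomogram_id", "dataset", "feature", "present")


class UnknownFeatureError(KeyError):
    """Requested feature does not appear in the catalog."""


def ratio_report(k: int, n: int, decimals: int = 0) -> str:
    """Render 100*k/n as a percent string at the requested precision.

    Rounding is round-half-even; ``(170, 186, 1)`` gives ``"91.4%"``.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    if k < 0 or k > n:
        raise ValueError(f"k must satisfy 0 <= k <= n, got k={k}, n={n}")
    if decimals < 0:
        raise ValueError("decimals must be nonnegative")
    value = round(100.0 * k / n, decimals)
    return f"{value:.{decimals}f}%"


def format_percent(k: int, n: int, decimals: int | None = None) -> str:
    """Percent string at the study's printed precision.

    Nearest integer when the fraction is at least 1% (or k = 0); one decimal
    below 1% or when ``decimals`` is given explicitly.
    """
    if decimals is None:
        decimals = 1 if 0 < 100.0 * k / max(n, 1) < 1.0 else 0
    return ratio_report(k, n, decimals)


@dataclass
class PrevalenceResult:
    feature: str
    k: int
    n: int
    fraction: float
    percent: str


def prevalence(catalog: pd.DataFrame, feature: str) -> PrevalenceResult:
    """Tally one feature over a tomogram catalog.

    ``catalog`` has one row per (tomogram, feature) with a ``present`` flag
    (or count; any nonzero counts as present).  ``n`` is the number of
    tomograms scored for the feature, ``k`` the number where it was present.
    """
    sub = catalog[catalog["feature"] == feature]
    if sub.empty:
        raise UnknownFeatureError(feature)
    if sub["tomogram_id"].duplicated().any():
        raise ValueError(f"feature {feature!r}: duplicate tomogram_id rows")
    n = int(len(sub))
    k = int((sub["present"].astype(float) != 0).sum())
    return PrevalenceResult(feature, k, n, k / n, format_percent(k, n))


def prevalence_table(catalog: pd.DataFrame) -> pd.DataFrame:
    """Prevalence of every feature in the catalog, one row per feature."""
    rows = []
    for feature in pd.unique(catalog["feature"]):
        r = prevalence(catalog, feature)
        rows.append(
            {"feature": r.feature, "k": r.k, "n": r.n, "fraction": r.fraction, "percent": r.percent}
        )
    return pd.DataFrame(rows, columns=["feature", "k", "n", "fraction", "percent"])


def prevalence_phrase(result: PrevalenceResult) -> str:
    """Plain-text ``(k/n, or p%)`` phrasing for reports."""
    return f"{result.feature} ({result.k}/{result.n}, or {result.percent})"


def load_catalog(path: str | os.PathLike) -> pd.DataFrame:
    """Read a feature catalog CSV with columns tomogram_id, dataset, feature, present."""
    catalog = pd.read_csv(path)
    missing = [c for c in CATALOG_COLUMNS if c not in catalog.columns]
    if missing:
        raise ValueError(f"catalog is missing columns: {missing}")
    return catalog
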