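"""Corrections and filters producing the analysis-ready rate matrix.

The raw, apparent first-order rate constants are influenced by two readily
quantified factors that are corrected for before any variability analysis:

* sorption — the apparent k is referenced to the freely dissolved
  concentration by dividing by the dissolved fraction;
* pH speciation — for ionizable chemicals, k is corrected to a reference pH
  of 7 via the ratio of the neutral fractions at the reference and at the
  experimental pH (Henderson–Hasselbalch closed form per site, multiprotic
  chemicals by the independent-site product approximation).

Remaining steps clean the matrix: per-chemical outlier removal on log10 k by
Tukey's interquartile-range fences, and a coverage filter keeping only
chemicals measured in at least a configurable fraction of the
site-experiments. TOC normalization is provided as a non-chemical baseline
for comparison with benchmarking.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, ValidationError
from .io import RateMatrix, RateRecord, RateTable, pivot_log_matrix

logger = logging.getLogger(__name__)


@dataclass
class PreprocessConfig:
    """Thresholds and switches for the preprocessing pipeline.

    ``iqr_multiplier`` — Tukey fence multiplier m: values outside
    [Q1 - m*IQR, Q3 + m*IQR] are outliers (default 1.5, the classic fences).
    ``coverage_fraction`` — keep chemicals with values in at least this
    fraction of site-experiments (default 0.5, i.e. at least half).
    ``min_values_for_outlier_test`` — below this many values per chemical the
    outlier test is skipped entirely (quartiles of a tiny sample are
    meaningless).
    ``outlier_scale`` — 'log' applies the IQR rule to log10 k (the analysis
    variable); 'raw' to k itself, for sensitivity analysis.
    """

    iqr_multiplier: float = 1.5
    coverage_fraction: float = 0.5
    reference_pH: float = 7.0
    apply_ph_correction: bool = True
    apply_dissolved_correction: bool = True
    min_values_for_outlier_test: int = 4
    outlier_scale: str = "log"

    def __post_init__(self) -> None:
        if not self.iqr_multiplier > 0:
            raise DomainError("iqr_multiplier must be positive")
        if not (0 < self.coverage_fraction <= 1):
            raise DomainError("coverage_fraction must be in (0, 1]")
        if not math.isfinite(self.reference_pH):
            raise DomainError("reference_pH must be finite")
        if self.min_values_for_outlier_test < 1:
            raise DomainError("min_values_for_outlier_test must be >= 1")
        if self.outlier_scale not in ("log", "raw"):
            raise DomainError("outlier_scale must be 'log' or 'raw'")


# ---------------------------------------------------------------------------
# per-record corrections
# ---------------------------------------------------------------------------


def dissolved_correct(k_apparent: float, f_dissolved: float) -> float:
    """Reference the rate constant to the freely dissolved concentration.

    Returns ``k_apparent / f_dissolved``; monotone decreasing in the
    dissolved fraction (stronger sorption -> larger correction).
    """
    if not (0 < f_dissolved <= 1):
        raise DomainError(f"f_dissolved {f_dissolved!r} outside (0, 1]")
    if not k_apparent > 0:
        raise DomainError(f"k_apparent {k_apparent!r} must be positive")
    return k_apparent / f_dissolved


def neutral_fraction(pH: float, pka_list: Iterable[tuple[float, str]]) -> float:
    """Fraction of the chemical in the neutral form at the given pH.

    Monoprotic acid: 1/(1+10^(pH-pKa)); monoprotic base: 1/(1+10^(pKa-pH));
    multiprotic chemicals use the independent-site product of the per-site
    factors. An empty ``pka_list`` (permanently neutral) gives 1.0.
    """
    if not math.isfinite(pH):
        raise DomainError(f"pH {pH!r} must be finite")
    frac = 1.0
    for pka, site_type in pka_list:
        if site_type == "acid":
            frac *= 1.0 / (1.0 + 10.0 ** (pH - pka))
        elif site_type == "base":
            frac *= 1.0 / (1.0 + 10.0 ** (pka - pH))
        else:
            raise DomainError(
                f"unknown speciation site type {site_type!r} "
                "(expected 'acid' or 'base')"
            )
    return frac


def ph_correct(
    k: float,
    pH_exp: float,
    pka_list: Iterable[tuple[float, str]],
    reference_pH: float = 7.0,
) -> float:
    """Correct k to the reference pH via the ratio of neutral fractions.

    k_ref = k * f_neutral(reference_pH) / f_neutral(pH_exp); the identity when
    the experiment was at the reference pH or the chemical never ionizes.
    """
    if not k > 0:
        raise DomainError(f"k {k!r} must be positive")
    pka_list = tuple(pka_list)
    return k * neutral_fraction(reference_pH, pka_list) / neutral_fraction(
        pH_exp, pka_list
    )


# ---------------------------------------------------------------------------
# matrix-level filters
# ---------------------------------------------------------------------------


def iqr_outlier_mask(
    values: Sequence[float] | np.ndarray,
    multiplier: float = 1.5,
    min_values: int = 4,
) -> np.ndarray:
    """Tukey-fence outlier mask (True = outlier) for one chemical's values.

    Quartiles use linear interpolation of order statistics (numpy's default,
    the 'type 7' rule). With fewer than ``min_values`` values nothing is
    flagged; with zero IQR, values differing from the median are flagged.
    """
    v = np.asarray(values, dtype=float)
    if not np.isfinite(v).all():
        raise DomainError("iqr_outlier_mask requires finite values")
    if not multiplier > 0:
        raise DomainError("multiplier must be positive")
    if v.size < min_values:
        return np.zeros(v.shape, dtype=bool)
    q1, q3 = np.quantile(v, [0.25, 0.75])
    iqr = q3 - q1
    if iqr == 0:
        return v != np.median(v)
    lo = q1 - multiplier * iqr
    hi = q3 + multiplier * iqr
    return (v < lo) | (v > hi)


def remove_outliers(
    matrix: RateMatrix,
    multiplier: float = 1.5,
    min_values: int = 4,
    scale: str = "log",
) -> tuple[RateMatrix, int]:
    """Blank per-chemical IQR outliers; returns (matrix, n cells removed)."""
    df = matrix.logk.copy()
    n_removed = 0
    for cid in df.index:
        row = df.loc[cid]
        present = row.notna().to_numpy()
        if present.sum() == 0:
            continue
        vals = row.to_numpy(dtype=float)[present]
        if scale == "raw":
            mask = iqr_outlier_mask(10.0 ** vals, multiplier, min_values)
        else:
            mask = iqr_outlier_mask(vals, multiplier, min_values)
        if mask.any():
            cols = np.asarray(df.columns)[present][mask]
            df.loc[cid, cols] = np.nan
            n_removed += int(mask.sum())
    return RateMatrix(df), n_removed


def coverage_filter(matrix: RateMatrix, coverage_fraction: float = 0.5) -> RateMatrix:
    """Keep chemicals with values in at least ceil(fraction * n_sites) sites.

    The site list is unchanged and the chemical order is preserved, so the
    operation is idempotent.
    """
    if not (0 < coverage_fraction <= 1):
        raise DomainError("coverage_fraction must be in (0, 1]")
    n_sites = len(matrix.sites)
    threshold = math.ceil(coverage_fraction * n_sites - 1e-12)
    counts = matrix.n_valid()
    keep = [c for c in matrix.chemicals if counts[c] >= threshold]
    return RateMatrix(matrix.logk.loc[keep].copy())


def toc_normalize(matrix: RateMatrix, toc_by_site: Mapping[str, float]) -> RateMatrix:
    """Normalize to total organic carbon: cell (i,j) -> log10 k_ij - log10 TOC_j.

    This is the benchmarking transform with log10 TOC in the role of the
    benchmark's log rate constant; the missingness pattern is unchanged.
    """
    df = matrix.logk.copy()
    for site in matrix.sites:
        if site not in toc_by_site:
            raise DomainError(f"no TOC value for site {site!r}")
        toc = toc_by_site[site]
        if not (toc > 0 and math.isfinite(toc)):
            raise DomainError(f"non-positive or non-finite TOC for site {site!r}")
        df[site] = df[site] - math.log10(toc)
    return RateMatrix(df)


# ---------------------------------------------------------------------------
# pipeline driver
# ---------------------------------------------------------------------------


@dataclass
class FilterLog:
    """Counts of what each preprocessing stage removed."""

    n_records: int = 0
    n_invalid: int = 0
    n_values_pivoted: int = 0
    n_outliers_removed: int = 0
    n_chemicals_before_coverage: int = 0
    n_chemicals_dropped: int = 0
    n_chemicals_final: int = 0
    n_values_final: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def _corrected_record(r: RateRecord, pka, config: PreprocessConfig) -> RateRecord:
    k = r.k_apparent
    if config.apply_dissolved_correction and r.f_dissolved is not None:
        k = dissolved_correct(k, r.f_dissolved)
    if config.apply_ph_correction and r.pH_exp is not None and pka:
        k = ph_correct(k, r.pH_exp, pka, config.reference_pH)
    if k == r.k_apparent:
        return r
    return RateRecord(
        chemical_id=r.chemical_id,
        site_id=r.site_id,
        k_apparent=k,
        valid=r.valid,
        pH_exp=r.pH_exp,
        f_dissolved=r.f_dissolved,
        toc=r.toc,
        replicate_stddev=r.replicate_stddev,
    )


def preprocess_table(table: RateTable, config: PreprocessConfig | None = None):
    """Run corrections and filters; returns (RateMatrix, FilterLog).

    Order of operations: dissolved-fraction correction -> pH correction ->
    log10 pivot -> per-chemical IQR outlier removal -> coverage filter.
    """
    if config is None:
        config = PreprocessConfig()
    log = FilterLog(n_records=len(table.records))
    log.n_invalid = sum(1 for r in table.records if not r.valid)
    corrected = RateTable(
        records=[
            _corrected_record(r, table.pka_for(r.chemical_id), config)
            for r in table.valid_records()
        ],
        meta=table.meta,
    )
    matrix = pivot_log_matrix(corrected)
    log.n_values_pivoted = matrix.n_values()
    matrix, log.n_outliers_removed = remove_outliers(
        matrix,
        multiplier=config.iqr_multiplier,
        min_values=config.min_values_for_outlier_test,
        scale=config.outlier_scale,
    )
    log.n_chemicals_before_coverage = len(matrix.chemicals)
    filtered = coverage_filter(matrix, config.coverage_fraction)
    log.n_chemicals_final = len(filtered.chemicals)
    log.n_chemicals_dropped = log.n_chemicals_before_coverage - log.n_chemicals_final
    log.n_values_final = filtered.n_values()
    logger.info(
        "preprocess: %d records (%d invalid) -> %d values; %d outliers removed; "
        "%d/%d chemicals kept; %d values final",
        log.n_records,
        log.n_invalid,
        log.n_values_pivoted,
        log.n_outliers_removed,
        log.n_chemicals_final,
        log.n_chemicals_before_coverage,
        log.n_values_final,
    )
    return filtered, log
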