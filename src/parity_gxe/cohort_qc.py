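"""Registry QC: sample selection, parity validation, phenotype filters.

Turns a registry-style pregnancy table into an analysis-ready per-stratum
cohort, with an audit trail attributing every excluded record to the first
filter that removed it.

Filter conventions (fixed and documented; every range check is inclusive at
both endpoints):

* gestational duration: singleton, non-ART, known sex, no malformation, no
  early perinatal death, spontaneous onset, 154 <= GD <= 308 days, child
  survived the first year.
* birth weight: singleton, non-ART, known sex, no malformation, no early
  perinatal death, then 259 <= GD <= 300 days, then a single-pass +/- 5 SD
  trim with mean/SD computed on the records surviving the earlier filters.
  Birth weight enters all analyses as a z-score using that mean/SD.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GD_RANGE_DAYS = (154, 308)
BW_GD_RANGE_DAYS = (259, 300)
BW_SD_LIMIT = 5.0

REQUIRED_COLUMNS = [
    "mother_id",
    "delivery_order",
    "parity",
    "gestational_duration",
    "birth_weight",
    "sex",
    "art",
    "plurality",
    "malformation",
    "perinatal_death",
    "death_first_year",
    "spontaneous_onset",
]


class SchemaError(KeyError):
    """A required registry column is missing."""


@dataclass
class QcReport:
    """Per-filter removal counts; each record counted once, at the first
    filter that removes it, in the documented filter order."""

    counts: dict[str, int] = field(default_factory=dict)
    n_in: int = 0
    n_out: int = 0

    def to_json(self) -> str:
        return json.dumps(
            {"n_in": self.n_in, "n_out": self.n_out, "removed": self.counts}, indent=2
        )

    def __str__(self) -> str:
        lines = [f"records in: {self.n_in}"]
        for name, k in self.counts.items():
            lines.append(f"  removed by {name}: {k}")
        lines.append(f"records out: {self.n_out}")
        return "\n".join(lines)


@dataclass
class AnalysisCohort:
    """Per-sample analysis rows: phenotype value (days or z-score), stratum
    ('first' iff parity 0), and covariates, after all QC."""

    rows: pd.DataFrame
    phenotype_name: str
    bw_mean: float | None = None
    bw_sd: float | None = None


def _check_schema(records: pd.DataFrame, needed: list[str]) -> None:
    missing = [c for c in needed if c not in records.columns]
    if missing:
        raise SchemaError(f"registry table is missing columns: {missing}")


# ---------------------------------------------------------------------------
# parity validation and one-pregnancy selection
# ---------------------------------------------------------------------------


def validate_parity(records: pd.DataFrame) -> set[str]:
    """Mother ids with uncertain parity histories.

    A mother is flagged iff (a) two of her registered births share a parity
    value, or (b) her parities, sorted by delivery order, are not strictly
    increasing (e.g. a parity 0 after a parity 1).
    """
    if len(records) == 0:
        return set()
    _check_schema(records, ["mother_id", "delivery_order", "parity"])
    flagged: set[str] = set()
    for mid, grp in records.groupby("mother_id", sort=False):
        par = grp.sort_values("delivery_order")["parity"].to_numpy()
        if len(np.unique(par)) < len(par) or np.any(np.diff(par) <= 0):
            flagged.add(mid)
    return flagged


def select_one_pregnancy(records: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Keep exactly one record per mother, chosen uniformly at random.

    Deterministic under a fixed seed; guarantees no mother contributes to
    both parity strata downstream.
    """
    if len(records) == 0:
        return records.copy()
    _check_schema(records, ["mother_id"])
    rng = np.random.default_rng(seed)
    # stable order first so the draw depends only on (content, seed)
    rec = records.sort_values(["mother_id", "delivery_order"], kind="mergesort")
    keep_idx = []
    for _, grp in rec.groupby("mother_id", sort=True):
        keep_idx.append(grp.index[rng.integers(0, len(grp))])
    return records.loc[sorted(keep_idx)].copy()


# ---------------------------------------------------------------------------
# phenotype filters
# ---------------------------------------------------------------------------

_SHARED_FILTERS = [
    ("plurality", lambda r: r["plurality"] != 1),
    ("art", lambda r: r["art"].astype(bool)),
    ("unknown_sex", lambda r: r["sex"] == "unknown"),
    ("malformation", lambda r: r["malformation"].astype(bool)),
    ("perinatal_death", lambda r: r["perinatal_death"].astype(bool)),
]


def _apply_filters(records: pd.DataFrame, filters) -> tuple[pd.DataFrame, QcReport]:
    report = QcReport(n_in=len(records))
    kept = records
    for name, rule in filters:
        bad = rule(kept)
        report.counts[name] = int(bad.sum())
        kept = kept.loc[~bad]
    report.n_out = len(kept)
    return kept.copy(), report


def filter_gestational_duration(records: pd.DataFrame) -> tuple[pd.DataFrame, QcReport]:
    """Inclusion rules for the gestational-duration analyses (bounds inclusive)."""
    _check_schema(records, REQUIRED_COLUMNS)
    lo, hi = GD_RANGE_DAYS
    filters = _SHARED_FILTERS + [
        ("non_spontaneous", lambda r: ~r["spontaneous_onset"].astype(bool)),
        ("gd_range", lambda r: ~r["gestational_duration"].between(lo, hi)),
        ("death_first_year", lambda r: r["death_first_year"].astype(bool)),
    ]
    return _apply_filters(records, filters)


def filter_birth_weight(
    records: pd.DataFrame,
) -> tuple[pd.DataFrame, QcReport, float, float]:
    """Inclusion rules for the birth-weight analyses.

    Shared exclusions, then the 259-300 day gestational window, then a
    single-pass +/- 5 SD trim around the mean of the surviving records.
    Returns the mean/SD used for the trim (and for the z-score transform).
    """
    _check_schema(records, REQUIRED_COLUMNS)
    lo, hi = BW_GD_RANGE_DAYS
    filters = _SHARED_FILTERS + [
        ("gd_range", lambda r: ~r["gestational_duration"].between(lo, hi)),
    ]
    kept, report = _apply_filters(records, filters)
    if len(kept) < 2:
        raise ValueError("fewer than 2 records survive the filters; SD undefined")
    bw = kept["birth_weight"].to_numpy(dtype=float)
    mean, sd = float(bw.mean()), float(bw.std(ddof=1))
    if sd == 0:
        raise ValueError("zero birth-weight SD; cannot apply the SD trim")
    bad = np.abs(bw - mean) > BW_SD_LIMIT * sd
    report.counts["bw_sd_trim"] = int(bad.sum())
    kept = kept.loc[~bad].copy()
    report.n_out = len(kept)
    return kept, report, mean, sd


def to_z_scores(values: np.ndarray) -> np.ndarray:
    """(x - mean)/SD with the n-1 SD; output has mean 0, SD 1."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values for a z-score transform")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero standard deviation; z-scores undefined")
    return (x - x.mean()) / sd


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------


def build_cohort(
    registry: pd.DataFrame,
    covariates: pd.DataFrame,
    phenotype: str,
    seed: int,
) -> tuple[AnalysisCohort, QcReport]:
    """Full QC chain: parity validation -> one random pregnancy per mother ->
    phenotype-specific filters -> (for birth weight) z-score transform.

    The returned rows carry ``sample_id`` (= mother id), ``phenotype_value``,
    ``stratum`` and the covariate columns, merged on sample id.
    """
    _check_schema(registry, REQUIRED_COLUMNS)
    n_in = len(registry)
    bad_mothers = validate_parity(registry)
    rec = registry.loc[~registry["mother_id"].isin(bad_mothers)]
    n_parity = n_in - len(rec)
    rec = select_one_pregnancy(rec, seed=seed)
    n_multi = n_in - n_parity - len(rec)

    bw_mean = bw_sd = None
    if phenotype == "gestational_duration":
        kept, rep = filter_gestational_duration(rec)
        values = kept["gestational_duration"].to_numpy(dtype=float)
    elif phenotype == "birth_weight":
        kept, rep, _, _ = filter_birth_weight(rec)
        # study-population mean/SD, i.e. of the final included set
        bw = kept["birth_weight"].to_numpy(dtype=float)
        bw_mean, bw_sd = float(bw.mean()), float(bw.std(ddof=1))
        values = to_z_scores(bw)
    else:
        raise ValueError(f"unknown phenotype: {phenotype}")

    report = QcReport(
        counts={"uncertain_parity": n_parity, "extra_pregnancies": n_multi, **rep.counts},
        n_in=n_in,
        n_out=len(kept),
    )

    rows = pd.DataFrame(
        {
            "sample_id": kept["mother_id"].to_numpy(),
            "phenotype_value": values,
            "stratum": np.where(kept["parity"].to_numpy() == 0, "first", "later"),
        }
    )
    if phenotype == "birth_weight":
        # birth-weight models adjust for gestational duration
        rows["gestational_duration"] = kept["gestational_duration"].to_numpy(dtype=float)
    rows = rows.merge(covariates, on="sample_id", how="inner", validate="one_to_one")
    cohort = AnalysisCohort(
        rows=rows.reset_index(drop=True),
        phenotype_name=phenotype,
        bw_mean=bw_mean,
        bw_sd=bw_sd,
    )
    return cohort, report
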