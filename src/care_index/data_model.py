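"""Domain types and cohort-table handling.

A *cohort table* is one row per subject: identifiers, a conversion group
label (``N-MCI`` for stable MCI, ``P-MCI`` for subjects who progressed to
AD dementia within the follow-up window), demographics, and a panel of
biomarker measurements, any of which may be missing.  Files are plain
comma-delimited UTF-8; the missing-value token is ``NA`` (any case) or an
empty cell.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

N_MCI = "N-MCI"
P_MCI = "P-MCI"
GROUP_LABELS = (N_MCI, P_MCI)

#: columns every cohort file must carry besides the biomarker panel
REQUIRED_COLUMNS = ("subject_id", "group", "cohort")

_NA_TOKENS = ["NA", "na", "Na", "nA", ""]


class SchemaError(ValueError):
    """A cohort file does not have the required shape (missing column, bad header)."""


class ValidationError(ValueError):
    """A cohort file parses but violates an invariant (duplicate ids, bad labels)."""


class DegenerateReferenceError(ValueError):
    """A standardization reference has non-positive spread."""


@dataclass(frozen=True)
class BiomarkerSpec:
    """A biomarker and the direction its value moves as AD pathology accrues.

    ``direction="increase"`` means abnormally *high* values signal the event
    (e.g. hippocampal functional connectivity index, p-tau, ADAS-Cog);
    ``"decrease"`` means abnormally low values do (e.g. CSF Aβ1-42, MMSE).
    """

    name: str
    direction: str  # "increase" | "decrease"
    units: str = ""

    def __post_init__(self) -> None:
        if self.direction not in ("increase", "decrease"):
            raise ValueError(
                f"direction must be 'increase' or 'decrease', got {self.direction!r}"
            )


def canonical_panel() -> list[BiomarkerSpec]:
    """The ten-biomarker AD panel: three functional connectivity indices,
    two gray-matter concentration indices, two CSF assays, three cognitive
    scores, each with its established direction of abnormality."""
    return [
        BiomarkerSpec("HIP_FCI", "increase", "z"),
        BiomarkerSpec("PCC_FCI", "decrease", "z"),
        BiomarkerSpec("FG_FCI", "increase", "z"),
        BiomarkerSpec("HIP_GMI", "decrease", "a.u."),
        BiomarkerSpec("FG_GMI", "decrease", "a.u."),
        BiomarkerSpec("ABETA", "decrease", "pg/mL"),
        BiomarkerSpec("PTAU", "increase", "pg/mL"),
        BiomarkerSpec("MMSE", "decrease", "points"),
        BiomarkerSpec("ADAS", "increase", "points"),
        BiomarkerSpec("AVLT", "decrease", "points"),
    ]


def panel_names(panel: Sequence[BiomarkerSpec]) -> list[str]:
    return [b.name for b in panel]


def _check_panel(panel: Sequence[BiomarkerSpec]) -> None:
    names = panel_names(panel)
    if len(set(names)) != len(names):
        raise ValidationError(f"duplicate biomarker names in panel: {names}")


@dataclass
class CohortTable:
    """Validated per-subject table for one cohort.

    ``data`` holds one row per subject with at least :data:`REQUIRED_COLUMNS`
    plus the biomarker columns named by ``panel``.  Missing biomarker values
    are ``NaN``; they are never silently imputed.
    """

    cohort_id: str
    data: pd.DataFrame
    panel: list[BiomarkerSpec] = field(default_factory=canonical_panel)
    n_rejected_rows: int = 0

    def __post_init__(self) -> None:
        _check_panel(self.panel)
        for col in REQUIRED_COLUMNS:
            if col not in self.data.columns:
                raise SchemaError(f"required column missing: {col!r}")
        for name in panel_names(self.panel):
            if name not in self.data.columns:
                raise SchemaError(f"biomarker column missing: {name!r}")
        ids = self.data["subject_id"]
        if ids.duplicated().any():
            dupes = sorted(ids[ids.duplicated()].unique().tolist())
            raise ValidationError(f"duplicate subject_id values: {dupes}")
        bad = ~self.data["group"].isin(GROUP_LABELS)
        if bad.any():
            raise ValidationError(
                f"unrecognized group labels: {sorted(self.data.loc[bad, 'group'].unique())}"
            )
        self.data = self.data.reset_index(drop=True)

    @property
    def n_subjects(self) -> int:
        return len(self.data)

    @property
    def group_counts(self) -> dict[str, int]:
        counts = self.data["group"].value_counts()
        return {g: int(counts.get(g, 0)) for g in GROUP_LABELS}

    def biomarker_matrix(self, names: Sequence[str] | None = None) -> np.ndarray:
        """Float matrix (subjects x biomarkers), NaN where missing."""
        names = list(names) if names is not None else panel_names(self.panel)
        return self.data[names].to_numpy(dtype=float)

    def restrict_panel(self, names: Sequence[str]) -> "CohortTable":
        """A copy restricted to the biomarkers in ``names`` (cross-cohort
        harmonization: both cohorts are cut to the shared panel before any
        fitting or staging)."""
        keep = [b for b in self.panel if b.name in set(names)]
        cols = [c for c in self.data.columns if c not in panel_names(self.panel)]
        cols += [b.name for b in keep]
        return CohortTable(
            cohort_id=self.cohort_id,
            data=self.data[cols].copy(),
            panel=keep,
            n_rejected_rows=self.n_rejected_rows,
        )


def shared_panel(a: CohortTable, b: CohortTable) -> list[str]:
    """Biomarkers present in both cohorts' panels, in ``a``'s panel order."""
    b_names = set(panel_names(b.panel))
    return [n for n in panel_names(a.panel) if n in b_names]


def read_cohort(
    path: str | Path | io.IOBase,
    panel: Sequence[BiomarkerSpec] | None = None,
    cohort_id: str | None = None,
) -> CohortTable:
    """Read and validate a cohort CSV.

    Rows whose group label is not ``N-MCI``/``P-MCI`` are dropped and counted
    in ``n_rejected_rows``.  Missing biomarker cells (``NA`` or empty) are
    preserved as NaN.
    """
    panel = list(panel) if panel is not None else canonical_panel()
    df = pd.read_csv(path, na_values=_NA_TOKENS, keep_default_na=False, dtype=str)
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"required column missing: {col!r}")
    for name in panel_names(panel):
        if name not in df.columns:
            raise SchemaError(f"biomarker column missing: {name!r}")
    good = df["group"].isin(GROUP_LABELS)
    n_rejected = int((~good).sum())
    df = df[good].copy()
    numeric_like = [c for c in df.columns if c not in ("subject_id", "group", "cohort", "sex")]
    for col in numeric_like:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    if cohort_id is None:
        ids = df["cohort"].dropna().unique() if len(df) else []
        cohort_id = str(ids[0]) if len(ids) else "unknown"
    return CohortTable(cohort_id=cohort_id, data=df, panel=panel, n_rejected_rows=n_rejected)


def write_cohort(table: CohortTable, path: str | Path) -> None:
    """Write a cohort CSV that :func:`read_cohort` round-trips bit-exactly
    (missing cells as ``NA``, floats at full precision)."""
    table.data.to_csv(path, index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# composite cognitive z-scores


@dataclass
class CognitiveDomainMap:
    """Assignment of neuropsychological tests to cognitive domains
    (episodic memory, information processing speed, executive function,
    visuospatial function).  Each test may appear in at most one domain.
    The exact assignment is site-specific, so it is configuration, not code.
    """

    domains: dict[str, list[str]]

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for domain, tests in self.domains.items():
            for t in tests:
                if t in seen:
                    raise ValidationError(
                        f"test {t!r} assigned to both {seen[t]!r} and {domain!r}"
                    )
                seen[t] = domain

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CognitiveDomainMap":
        with open(path) as fh:
            return cls(yaml.safe_load(fh))


def composite_z(
    table: CohortTable,
    domain_map: CognitiveDomainMap,
    reference: Mapping[str, tuple[float, float]] | None = None,
    higher_worse: Iterable[str] = (),
) -> pd.DataFrame:
    """Per-subject composite z-score for each cognitive domain.

    Each test is standardized against reference moments (mean, sd); tests in
    ``higher_worse`` (e.g. completion times) are sign-flipped so that higher
    always means better; the domain score is the mean of the subject's
    available standardized tests.  When ``reference`` is None the combined
    baseline sample of this table provides the moments.

    Returns a DataFrame indexed by subject_id with one column per domain;
    NaN where a subject has no available test in a domain.
    """
    flip = set(higher_worse)
    all_tests = [t for tests in domain_map.domains.values() for t in tests]
    for t in all_tests:
        if t not in table.data.columns:
            raise SchemaError(f"test column missing: {t!r}")
    if reference is None:
        reference = {
            t: (float(table.data[t].mean()), float(table.data[t].std(ddof=1)))
            for t in all_tests
        }
    z_cols: dict[str, pd.Series] = {}
    for t in all_tests:
        mean, sd = reference[t]
        if not sd > 0:
            raise DegenerateReferenceError(f"reference sd for {t!r} must be > 0, got {sd}")
        z = (pd.to_numeric(table.data[t], errors="coerce") - mean) / sd
        z_cols[t] = -z if t in flip else z
    out = {}
    for domain, tests in domain_map.domains.items():
        out[domain] = pd.concat([z_cols[t] for t in tests], axis=1).mean(axis=1)
    result = pd.DataFrame(out)
    result.index = pd.Index(table.data["subject_id"], name="subject_id")
    return result


def change_scores(
    baseline: CohortTable,
    followup: CohortTable,
    variables: Sequence[str],
) -> tuple[pd.DataFrame, int]:
    """Follow-up minus baseline for each named variable.

    Subjects present at only one wave are dropped; the second return value
    counts them.  Raises if the waves share no subjects.
    """
    for var in variables:
        for tab, wave in ((baseline, "baseline"), (followup, "followup")):
            if var not in tab.data.columns:
                raise SchemaError(f"variable {var!r} missing from {wave} table")
    base = baseline.data.set_index("subject_id")
    fup = followup.data.set_index("subject_id")
    common = base.index.intersection(fup.index)
    if len(common) == 0:
        raise ValidationError("baseline and follow-up share no subject_ids")
    n_dropped = (len(base) - len(common)) + (len(fup) - len(common))
    delta = pd.DataFrame(
        {
            var: pd.to_numeric(fup.loc[common, var], errors="coerce")
            - pd.to_numeric(base.loc[common, var], errors="coerce")
            for var in variables
        },
        index=common,
    )
    delta.index.name = "subject_id"
    return delta, int(n_dropped)


def load_panel(path: str | Path) -> list[BiomarkerSpec]:
    """Panel from YAML: a list of ``{name, direction, units}`` mappings."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    panel = [BiomarkerSpec(d["name"], d["direction"], d.get("units", "")) for d in raw]
    _check_panel(panel)
    return panel


def save_panel(panel: Sequence[BiomarkerSpec], path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(
            [{"name": b.name, "direction": b.direction, "units": b.units} for b in panel],
            fh,
            sort_keys=False,
        )
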