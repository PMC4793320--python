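"""Reading, validation and cleaning of morphometric trait tables.

The universal input is a specimen-level CSV/TSV table with a unique
``specimen_id``, a ``nest_id`` grouping column, optional ``species``/``lat``/
``lon`` metadata and one column per trait code in micrometres.  Blank cells
mean "not measured", never zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .catalog import DEFAULT_CATALOG, TraitCatalog
from .errors import ValidationError

__all__ = [
    "MorphoTable",
    "CorrelationReport",
    "read_morpho_table",
    "write_morpho_table",
    "derive_cs",
    "ratio_table",
    "correlation_screen",
    "standardize",
]

ID_COLUMN = "specimen_id"
NEST_COLUMN = "nest_id"
OPTIONAL_COLUMNS = ("species", "lat", "lon")

_CS_RTOL = 1e-6


@dataclass
class MorphoTable:
    """Specimen x trait matrix with nest grouping.

    ``data`` is indexed by specimen id and holds ``nest_id``, the optional
    metadata columns, the trait columns (float, NaN = absent) and any unknown
    columns from the source file (preserved untouched, listed in ``extra``).
    """

    data: pd.DataFrame
    trait_columns: list[str] = field(default_factory=list)
    extra: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    # -- accessors ---------------------------------------------------------

    @property
    def specimen_ids(self) -> pd.Index:
        return self.data.index

    @property
    def nest_ids(self) -> pd.Series:
        return self.data[NEST_COLUMN]

    @property
    def species(self) -> pd.Series | None:
        return self.data["species"] if "species" in self.data.columns else None

    def __len__(self) -> int:
        return len(self.data)

    def traits(self, codes: list[str] | None = None, *, dropna: bool = False) -> pd.DataFrame:
        """Trait sub-frame; ``dropna`` drops specimens with any absent value."""
        codes = list(codes) if codes is not None else list(self.trait_columns)
        missing = [c for c in codes if c not in self.trait_columns]
        if missing:
            raise ValidationError(f"unknown trait columns requested: {missing}")
        frame = self.data[codes].astype(float)
        return frame.dropna() if dropna else frame

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dups = sorted(df.index[df.index.duplicated()].unique().tolist())
            raise ValidationError(f"duplicate specimen_id values: {dups}")
        if NEST_COLUMN not in df.columns:
            raise ValidationError("nest_id column is required")
        nulls = df[NEST_COLUMN].isna()
        if nulls.any():
            bad = df.index[nulls].tolist()
            raise ValidationError(f"missing nest_id for specimens: {bad}")
        for code in self.trait_columns:
            col = pd.to_numeric(df[code], errors="coerce")
            bad_numeric = df[code].notna() & col.isna()
            if bad_numeric.any():
                row = df.index[bad_numeric][0]
                raise ValidationError(
                    f"non-numeric trait value in column {code!r}, row {row!r}")
            nonpos = col.notna() & ~(col > 0)
            if nonpos.any():
                row = df.index[nonpos][0]
                raise ValidationError(
                    f"non-positive trait value in column {code!r}, row {row!r}")
            if not np.isfinite(col.dropna()).all():
                raise ValidationError(f"non-finite trait value in column {code!r}")
            self.data[code] = col
        if "CS" in self.trait_columns and {"CL", "CWb"} <= set(self.trait_columns):
            cs = df["CS"].astype(float)
            expect = (df["CL"].astype(float) + df["CWb"].astype(float)) / 2.0
            ok = cs.isna() | np.isclose(cs, expect, rtol=_CS_RTOL, atol=1e-9)
            if not ok.all():
                row = df.index[~ok][0]
                raise ValidationError(
                    f"CS != (CL+CWb)/2 for specimen {row!r}")

    def copy(self) -> "MorphoTable":
        return MorphoTable(self.data.copy(), list(self.trait_columns), list(self.extra))


def read_morpho_table(path: str | Path, dialect: str = "csv",
                      catalog: TraitCatalog = DEFAULT_CATALOG) -> MorphoTable:
    """Read and validate a specimen table from CSV or TSV.

    Unknown columns are preserved as metadata.  Blank trait cells become
    absent values (NaN), not zero.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"input file not found: {path}")
    if dialect not in ("csv", "tsv"):
        raise ValidationError(f"unknown dialect {dialect!r}; use 'csv' or 'tsv'")
    sep = "," if dialect == "csv" else "\t"
    df = pd.read_csv(path, sep=sep, dtype={ID_COLUMN: str, NEST_COLUMN: str})
    for required in (ID_COLUMN, NEST_COLUMN):
        if required not in df.columns:
            raise ValidationError(f"required column {required!r} missing in {path}")
    trait_cols = [c for c in df.columns if c in catalog]
    if not trait_cols:
        raise ValidationError(f"no known trait columns found in {path}")
    extra = [c for c in df.columns
             if c not in trait_cols and c not in (ID_COLUMN, NEST_COLUMN)
             and c not in OPTIONAL_COLUMNS]
    df = df.set_index(ID_COLUMN)
    return MorphoTable(df, trait_cols, extra)


def write_morpho_table(table: MorphoTable, path: str | Path, dialect: str = "csv") -> None:
    sep = "," if dialect == "csv" else "\t"
    out = table.data.reset_index()
    out = out.rename(columns={out.columns[0]: ID_COLUMN})
    out.to_csv(path, sep=sep, index=False, float_format="%.17g")


def derive_cs(table: MorphoTable) -> MorphoTable:
    """Add/overwrite the CS column as (CL + CWb) / 2."""
    for code in ("CL", "CWb"):
        if code not in table.trait_columns:
            raise ValidationError(f"cannot derive CS: column {code!r} absent")
        absent = table.data[code].isna()
        if absent.any():
            ids = table.data.index[absent].tolist()
            raise ValidationError(f"cannot derive CS: {code} absent for specimens {ids}")
    out = table.copy()
    out.data["CS"] = (out.data["CL"].astype(float) + out.data["CWb"].astype(float)) / 2.0
    if "CS" not in out.trait_columns:
        out.trait_columns.append("CS")
    return out


def ratio_table(table: MorphoTable, denominator: str,
                numerators: list[str]) -> pd.DataFrame:
    """Dimensionless ratio columns ``num/denominator`` per specimen.

    Specimens with an absent numerator get an absent ratio.
    """
    if not numerators:
        raise ValidationError("numerators list is empty")
    if denominator not in table.trait_columns:
        raise ValidationError(f"denominator {denominator!r} not in table")
    den = table.data[denominator].astype(float)
    if den.isna().any():
        ids = table.data.index[den.isna()].tolist()
        raise ValidationError(f"denominator {denominator!r} absent for specimens {ids}")
    cols = {}
    for num in numerators:
        if num not in table.trait_columns:
            raise ValidationError(f"numerator {num!r} not in table")
        cols[f"{num}/{denominator}"] = table.data[num].astype(float) / den
    return pd.DataFrame(cols, index=table.data.index)


def standardize(frame: pd.DataFrame) -> pd.DataFrame:
    """Center and scale each column to mean 0 and sample SD 1 (ddof=1)."""
    frame = frame.astype(float)
    if len(frame) < 2:
        raise ValidationError("standardize needs at least 2 rows")
    sd = frame.std(ddof=1)
    constant = sd[~(sd > 0)].index.tolist()
    if constant:
        raise ValidationError(f"constant columns cannot be standardized: {constant}")
    return (frame - frame.mean()) / sd


@dataclass
class CorrelationReport:
    """Per-trait summary of pooled within-class Pearson correlations."""

    traits: list[str]
    mean_r: dict[str, float]          # mean pooled r against all other traits
    min_r: dict[str, float]
    pooled_r: pd.DataFrame            # trait x trait pooled correlation matrix
    flagged: list[str]                # traits with mean pooled r < threshold
    threshold: float
    classes_used: list[str]

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "threshold": self.threshold,
            "classes_used": self.classes_used,
            "traits": [
                {
                    "code": t,
                    "mean_within_class_r": self.mean_r[t],
                    "min_within_class_r": self.min_r[t],
                    "flagged": t in self.flagged,
                }
                for t in self.traits
            ],
            "flagged": self.flagged,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


def correlation_screen(table: MorphoTable, class_labels: pd.Series | None = None,
                       threshold: float = 0.2,
                       traits: list[str] | None = None) -> CorrelationReport:
    """Error-variance screen via pooled within-class Pearson correlations.

    For every trait pair the within-class correlation is computed in each
    class with >= 3 complete specimens and pooled across classes weighted by
    (n_class - 1).  A trait whose mean pooled correlation against all other
    traits falls below ``threshold`` is flagged as a candidate measurement
    artifact.  Flagging is advisory; dropping the column is the caller's
    decision.

    ``class_labels`` defaults to species labels when present, else nest ids.
    """
    if class_labels is None:
        sp = table.species
        labels = sp if sp is not None and sp.notna().all() else table.nest_ids
    else:
        labels = pd.Series(class_labels, index=table.data.index)
    codes = traits if traits is not None else [
        c for c in table.trait_columns if table.data[c].notna().all()]
    if len(codes) < 2:
        raise ValidationError("correlation screen needs at least 2 complete traits")
    X = table.traits(codes)

    p = len(codes)
    num = np.zeros((p, p))
    den = 0.0
    used: list[str] = []
    for cls, idx in X.groupby(labels).groups.items():
        sub = X.loc[idx].to_numpy(float)
        if sub.shape[0] < 3:
            continue
        sds = sub.std(axis=0, ddof=1)
        if np.any(sds == 0):
            continue  # degenerate class: no correlation information
        r = np.corrcoef(sub, rowvar=False)
        w = sub.shape[0] - 1
        num += w * r
        den += w
        used.append(str(cls))
    if den == 0:
        raise ValidationError(
            "no class with >= 3 specimens and non-degenerate traits; "
            "cannot run the correlation screen")
    pooled = num / den
    np.fill_diagonal(pooled, 1.0)
    off = pooled.copy()
    np.fill_diagonal(off, np.nan)
    mean_r = {c: float(np.nanmean(off[i])) for i, c in enumerate(codes)}
    min_r = {c: float(np.nanmin(off[i])) for i, c in enumerate(codes)}
    flagged = [c for c in codes if mean_r[c] < threshold]
    pooled_df = pd.DataFrame(pooled, index=codes, columns=codes)
    return CorrelationReport(list(codes), mean_r, min_r, pooled_df, flagged,
                             threshold, sorted(used))
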