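"""Long-format isotope tables and dense sample x amino-acid matrices.

The canonical on-disk format is a UTF-8, RFC-4180 CSV in long format with
one row per (sample, amino acid, element) and columns::

    sample_id, fraction, treatment, study, genet,
    amino_acid, element, delta, sd, n_rep

``delta`` is the isotope ratio in per-mil (vs V-PDB for carbon, vs Air for
nitrogen); ``sd`` is the standard deviation over analytical replicate
injections and ``n_rep`` their count.  Column names can be remapped
through a schema dictionary (e.g. loaded from a YAML config), so tables
exported by other pipelines load without editing.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .registry import AminoAcidRegistry, DEFAULT_REGISTRY, RegistryError

__all__ = [
    "FRACTIONS",
    "SchemaError",
    "IntegrityError",
    "SampleRecord",
    "AAIsotopeTable",
    "SampleMatrix",
    "read_isotope_table",
    "write_isotope_table",
    "subset_matrix",
]

#: Closed vocabulary of tissue fractions / sample types.
FRACTIONS = ("host", "symbiont", "holobiont", "plankton", "POM", "microalgae")

REQUIRED_COLUMNS = ("sample_id", "fraction", "amino_acid", "element", "delta", "sd", "n_rep")
OPTIONAL_COLUMNS = ("treatment", "study", "genet")
ALL_COLUMNS = ("sample_id", "fraction", "treatment", "study", "genet",
               "amino_acid", "element", "delta", "sd", "n_rep")


class SchemaError(ValueError):
    """Input table does not match the expected schema."""


class IntegrityError(ValueError):
    """Input table violates a data invariant (duplicates, bad values)."""


@dataclass(frozen=True)
class SampleRecord:
    """Per-sample metadata."""

    sample_id: str
    fraction: str
    treatment: str | None = None
    study: str | None = None
    genet: str | None = None

    def __post_init__(self) -> None:
        if self.fraction not in FRACTIONS:
            raise IntegrityError(
                f"fraction {self.fraction!r} for sample {self.sample_id!r} "
                f"not in {FRACTIONS}"
            )


class AAIsotopeTable:
    """Validated long-format store of per-sample, per-AA isotope values.

    Parameters
    ----------
    data
        Long-format frame containing at least :data:`REQUIRED_COLUMNS`.
        Amino-acid codes are normalized against ``registry`` (case
        folding, Glu→Glx aliasing) on construction.
    registry
        Amino-acid vocabulary; rows with unknown codes are rejected.
    """

    def __init__(self, data: pd.DataFrame, registry: AminoAcidRegistry = DEFAULT_REGISTRY):
        missing = [c for c in REQUIRED_COLUMNS if c not in data.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {', '.join(missing)}")
        df = data.copy()
        for col in OPTIONAL_COLUMNS:
            if col not in df.columns:
                df[col] = None
        df = df.loc[:, list(ALL_COLUMNS)].reset_index(drop=True)

        # numeric coercion with row-level diagnostics
        for col in ("delta", "sd"):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = df.index[coerced.isna() & df[col].notna()]
            if len(bad):
                raise IntegrityError(
                    f"unparseable numeric in column {col!r} at row(s) {list(bad[:5])}"
                )
            df[col] = coerced.astype(float)
        n_rep = pd.to_numeric(df["n_rep"], errors="coerce")
        if n_rep.isna().any():
            raise IntegrityError(
                f"unparseable n_rep at row(s) {list(df.index[n_rep.isna()][:5])}"
            )
        df["n_rep"] = n_rep.astype(int)

        df["amino_acid"] = [registry.normalize(c) for c in df["amino_acid"]]
        df["element"] = df["element"].astype(str).str.upper()
        if not df["element"].isin(["C", "N"]).all():
            bad = sorted(set(df.loc[~df["element"].isin(["C", "N"]), "element"]))
            raise IntegrityError(f"element must be 'C' or 'N'; got {bad}")
        if (df["sd"] < 0).any():
            raise IntegrityError("replicate sd must be >= 0")
        if (df["n_rep"] < 1).any():
            raise IntegrityError("n_rep must be >= 1")
        if df["delta"].isna().any():
            raise IntegrityError("delta values may not be missing")

        key = df[["sample_id", "amino_acid", "element"]]
        if key.duplicated().any():
            dup = key[key.duplicated()].iloc[0].tolist()
            raise IntegrityError(f"duplicate (sample_id, amino_acid, element) key: {dup}")

        meta = df[["sample_id", "fraction", "treatment", "study", "genet"]].drop_duplicates()
        if meta["sample_id"].duplicated().any():
            bad = meta.loc[meta["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise IntegrityError(f"inconsistent metadata for sample {bad!r}")
        for rec in meta.itertuples(index=False):
            SampleRecord(rec.sample_id, rec.fraction, rec.treatment, rec.study, rec.genet)

        self._data = df
        self.registry = registry

    # -- accessors -------------------------------------------------------
    @property
    def data(self) -> pd.DataFrame:
        """The validated long-format frame (copy)."""
        return self._data.copy()

    @property
    def samples(self) -> pd.DataFrame:
        """Per-sample metadata, one row per sample_id."""
        return (
            self._data[["sample_id", "fraction", "treatment", "study", "genet"]]
            .drop_duplicates()
            .reset_index(drop=True)
        )

    def __len__(self) -> int:
        return len(self._data)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AAIsotopeTable):
            return NotImplemented
        a = self._data.sort_values(["sample_id", "element", "amino_acid"]).reset_index(drop=True)
        b = other._data.sort_values(["sample_id", "element", "amino_acid"]).reset_index(drop=True)
        if not a[["sample_id", "amino_acid", "element"]].equals(b[["sample_id", "amino_acid", "element"]]):
            return False
        num_ok = np.allclose(a[["delta", "sd"]], b[["delta", "sd"]], atol=1e-12) and (
            a["n_rep"] == b["n_rep"]
        ).all()
        meta_ok = a[["fraction", "treatment", "study", "genet"]].fillna("").equals(
            b[["fraction", "treatment", "study", "genet"]].fillna("")
        )
        return bool(num_ok and meta_ok)

    def value(self, sample_id: str, aa: str, element: str) -> tuple[float, float]:
        """(delta, sd) for one cell; raises ``KeyError`` if absent."""
        aa = self.registry.normalize(aa)
        sel = self._data[
            (self._data["sample_id"] == sample_id)
            & (self._data["amino_acid"] == aa)
            & (self._data["element"] == element.upper())
        ]
        if sel.empty:
            raise KeyError(f"no value for ({sample_id}, {aa}, {element})")
        row = sel.iloc[0]
        return float(row["delta"]), float(row["sd"])

    # -- IO --------------------------------------------------------------
    def to_csv(self, path) -> None:
        write_isotope_table(self, path)


def _apply_schema(df: pd.DataFrame, schema: Mapping[str, str] | None) -> pd.DataFrame:
    if schema:
        rename = {src: canonical for canonical, src in schema.items()}
        df = df.rename(columns=rename)
    return df


def read_isotope_table(
    source,
    schema: Mapping[str, str] | None = None,
    registry: AminoAcidRegistry = DEFAULT_REGISTRY,
) -> AAIsotopeTable:
    """Read a long-format isotope CSV into a validated table.

    ``schema`` maps canonical column names to the names used in the file,
    e.g. ``{"sample_id": "Sample", "delta": "d13C"}``.
    """
    df = pd.read_csv(source)
    df = _apply_schema(df, schema)
    return AAIsotopeTable(df, registry=registry)


def write_isotope_table(table: AAIsotopeTable, path) -> None:
    """Write the canonical CSV dialect (UTF-8, header, full precision)."""
    df = table.data
    df.to_csv(path, index=False, float_format="%.10g")


@dataclass
class SampleMatrix:
    """Dense samples x amino-acids grid for one element.

    Missing cells are carried in an explicit boolean ``mask`` (True =
    missing), never as a sentinel value.
    """

    values: np.ndarray
    mask: np.ndarray
    sample_ids: list[str]
    aa_codes: list[str]
    element: str
    metadata: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != (len(self.sample_ids), len(self.aa_codes)):
            raise ValueError("grid dimensions do not match label counts")
        if self.mask.shape != self.values.shape:
            raise ValueError("mask shape does not match values")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if len(set(self.aa_codes)) != len(self.aa_codes):
            raise ValueError("duplicate amino-acid codes")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def complete(self) -> bool:
        return not self.mask.any()

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.sample_ids, columns=self.aa_codes)
        return df.mask(pd.DataFrame(self.mask, index=self.sample_ids, columns=self.aa_codes))

    def groups(self, column: str = "fraction") -> pd.Series:
        """Metadata column aligned to matrix row order."""
        meta = self.metadata.set_index("sample_id")
        return meta.loc[self.sample_ids, column]


def subset_matrix(
    table: AAIsotopeTable,
    element: str,
    aa_set: Sequence[str],
    fractions: Iterable[str] | None = None,
    drop_missing_aas: bool = False,
    max_missing_fraction: float = 0.5,
) -> SampleMatrix:
    """Pivot a long table into a dense matrix for the requested panel.

    Parameters
    ----------
    aa_set
        Amino acids, in the desired column order; all must resolve in the
        table's registry.
    fractions
        Restrict samples to these tissue fractions (default: all).
    drop_missing_aas
        Drop any amino-acid column absent in at least one retained sample
        (supports panel intersections across studies, e.g. the 5-AA
        panel where lysine is unavailable).
    max_missing_fraction
        Without ``drop_missing_aas``, a column missing in more than this
        proportion of samples is an error.
    """
    element = element.upper()
    aa_codes = [table.registry.normalize(a) for a in aa_set]
    if len(set(aa_codes)) != len(aa_codes):
        raise ValueError("duplicate amino acids in aa_set")

    df = table.data
    df = df[df["element"] == element]
    if fractions is not None:
        fractions = list(fractions)
        unknown = set(fractions) - set(FRACTIONS)
        if unknown:
            raise ValueError(f"unknown fraction(s): {sorted(unknown)}")
        df = df[df["fraction"].isin(fractions)]
    if df.empty:
        raise ValueError("empty selection: no rows match element/fraction filter")

    sample_ids = list(dict.fromkeys(df["sample_id"]))
    wide = df.pivot(index="sample_id", columns="amino_acid", values="delta")
    wide = wide.reindex(index=sample_ids, columns=aa_codes)

    mask = wide.isna().to_numpy()
    if drop_missing_aas:
        keep = ~mask.any(axis=0)
        if not keep.any():
            raise ValueError("empty selection: every requested amino acid has missing cells")
        aa_codes = [c for c, k in zip(aa_codes, keep) if k]
        wide = wide.loc[:, aa_codes]
        mask = mask[:, keep]
    else:
        frac_missing = mask.mean(axis=0)
        over = [c for c, f in zip(aa_codes, frac_missing) if f > max_missing_fraction]
        if over:
            raise ValueError(
                f"amino acid(s) {over} missing in >{max_missing_fraction:.0%} of samples; "
                "pass drop_missing_aas=True to drop them"
            )

    meta = table.samples
    meta = meta[meta["sample_id"].isin(sample_ids)].reset_index(drop=True)
    return SampleMatrix(
        values=np.nan_to_num(wide.to_numpy(), nan=0.0),
        mask=mask,
        sample_ids=sample_ids,
        aa_codes=aa_codes,
        element=element,
        metadata=meta,
    )
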