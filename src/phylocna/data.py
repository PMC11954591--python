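"""I/O and derivations for copy-number tables, gene sets, phenotypes,
weights, and covariates.

File formats are deliberately plain: tab-separated count / phenotype /
annotation tables and standard GMT gene-set files.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CopyNumberMatrix",
    "GeneSetCollection",
    "PhenotypeTable",
    "read_counts",
    "write_counts",
    "read_annotation",
    "write_annotation",
    "filter_orthogroups",
    "read_gmt",
    "write_gmt",
    "map_sets_to_orthogroups",
    "aggregate_set_counts",
    "derive_cancer_phenotypes",
    "read_phenotypes",
    "proteome_covariate",
]

PHENOTYPE_RAW_COLUMNS = (
    "body_size_g",
    "longevity_months",
    "n_necropsies",
    "n_neoplasia",
    "n_malignant",
)


@dataclass
class CopyNumberMatrix:
    """Orthogroup x species copy-number counts plus reference-gene annotation.

    ``counts`` is indexed by orthogroup id with one column per species.
    ``annotation`` maps orthogroup ids to the reference-species gene symbols
    they contain (possibly empty for unannotated orthogroups).
    """

    counts: pd.DataFrame
    annotation: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self):
        counts = self.counts
        if counts.index.has_duplicates:
            dup = counts.index[counts.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate orthogroup ids: {dup}")
        if counts.columns.has_duplicates:
            dup = counts.columns[counts.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate species: {dup}")
        arr = counts.to_numpy()
        if np.isnan(arr.astype(float)).any():
            r, c = np.argwhere(np.isnan(arr.astype(float)))[0]
            raise ValueError(
                f"missing count at orthogroup {counts.index[r]!r}, "
                f"species {counts.columns[c]!r}"
            )
        if (arr < 0).any() or (arr != np.round(arr)).any():
            bad = np.argwhere((arr < 0) | (arr != np.round(arr)))[0]
            r, c = bad
            raise ValueError(
                f"invalid count {arr[r, c]!r} at orthogroup "
                f"{counts.index[r]!r}, species {counts.columns[c]!r}: counts "
                "must be non-negative integers"
            )
        self.counts = counts.astype(np.int64)
        self.counts.index.name = "orthogroup_id"
        self.counts.columns.name = None
        self.annotation = {
            og: tuple(sym) for og, sym in self.annotation.items()
        }

    @property
    def orthogroup_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def species(self) -> list[str]:
        return list(self.counts.columns)

    def symbols_for(self, orthogroup_id: str) -> tuple[str, ...]:
        return self.annotation.get(orthogroup_id, ())


@dataclass
class GeneSetCollection:
    """Named gene sets (symbol lists) from e.g. a GMT file."""

    sets: dict[str, list[str]]
    source: str = ""

    def __post_init__(self):
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
            if any(not isinstance(m, str) or not m for m in members):
                raise ValueError(f"gene set {name!r} has blank member symbols")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def names(self) -> list[str]:
        return list(self.sets)


@dataclass
class PhenotypeTable:
    """Per-species phenotypes with derived cancer quantities and weights.

    Derived columns: ``neoplasia_prevalence`` (neoplasms per necropsy),
    ``malignancy_prevalence`` (malignant cases per necropsy),
    ``malignancy_rate`` (proportion of neoplasms malignant; NaN when a
    species has no recorded neoplasm), and ``weight`` (square root of the
    necropsy count).
    """

    table: pd.DataFrame

    def __post_init__(self):
        df = self.table
        missing = [c for c in PHENOTYPE_RAW_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"phenotype table missing columns: {missing}")
        if df.index.has_duplicates:
            raise ValueError("duplicate species in phenotype table")
        df.index.name = "species"

    @property
    def species(self) -> list[str]:
        return list(self.table.index)

    def column(self, name: str) -> pd.Series:
        return self.table[name]


# ---------------------------------------------------------------------------
# counts I/O
# ---------------------------------------------------------------------------


def read_counts(path: str | Path, annotation: dict | None = None) -> CopyNumberMatrix:
    """Read an orthogroup x species count table (TSV, header = species,
    first column = orthogroup id)."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.isna().any().any():
        row = df.index[df.isna().any(axis=1)][0]
        raise ValueError(f"ragged or incomplete row for orthogroup {row!r}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValueError(
            f"non-numeric count {df.iat[r, c]!r} at orthogroup "
            f"{df.index[r]!r}, species {df.columns[c]!r}"
        )
    numeric.index = numeric.index.astype(str)
    numeric.columns = numeric.columns.astype(str)
    return CopyNumberMatrix(counts=numeric, annotation=annotation or {})


def write_counts(M: CopyNumberMatrix, path: str | Path) -> None:
    M.counts.to_csv(path, sep="\t", index_label="orthogroup_id")


def read_annotation(path: str | Path) -> dict[str, tuple[str, ...]]:
    """Read an orthogroup -> comma-separated-symbols TSV (two columns)."""
    out: dict[str, tuple[str, ...]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if ln == 1 and parts[0].lower() in ("orthogroup_id", "orthogroup"):
                continue
            og = parts[0]
            symbols = ()
            if len(parts) > 1 and parts[1]:
                symbols = tuple(
                    s.strip() for s in parts[1].split(",") if s.strip()
                )
            out[og] = symbols
    return out


def write_annotation(annotation: dict[str, tuple[str, ...]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("orthogroup_id\tsymbols\n")
        for og, syms in annotation.items():
            fh.write(f"{og}\t{','.join(syms)}\n")


def filter_orthogroups(M: CopyNumberMatrix, min_frac: float = 0.5) -> CopyNumberMatrix:
    """Keep orthogroups with *strictly more* than ``min_frac`` of species
    having a nonzero copy number (so exactly 50% is excluded at the
    default)."""
    if not 0.0 <= min_frac < 1.0:
        raise ValueError(f"min_frac must lie in [0, 1), got {min_frac}")
    frac_nonzero = (M.counts > 0).mean(axis=1)
    keep = frac_nonzero > min_frac
    kept = M.counts.loc[keep]
    ann = {og: M.annotation[og] for og in kept.index if og in M.annotation}
    return CopyNumberMatrix(counts=kept, annotation=ann)


# ---------------------------------------------------------------------------
# gene sets
# ---------------------------------------------------------------------------


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: one set per line, ``name<TAB>description<TAB>members``.

    Duplicate members within a set are dropped (first occurrence wins);
    the description field (often a URL in MSigDB exports) is ignored.
    """
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"GMT format error on line {ln}: expected at least 3 "
                    f"tab-separated fields, got {len(parts)}"
                )
            name = parts[0]
            members = list(dict.fromkeys(m for m in parts[2:] if m))
            sets[name] = members
    return GeneSetCollection(sets=sets, source=str(path))


def write_gmt(sets: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in sets.sets.items():
            fh.write("\t".join([name, "na", *members]) + "\n")


def map_sets_to_orthogroups(
    sets: GeneSetCollection, M: CopyNumberMatrix
) -> dict[str, list[str]]:
    """Map each gene set to the orthogroups annotated with any of its member
    symbols (case-insensitive).  Sets mapping to zero orthogroups are
    flagged with a warning and dropped."""
    if not any(M.annotation.values()):
        raise ValueError("no orthogroup annotation available for mapping")
    symbol_to_ogs: dict[str, list[str]] = {}
    for og, symbols in M.annotation.items():
        if og not in M.counts.index:
            continue
        for sym in symbols:
            symbol_to_ogs.setdefault(sym.casefold(), []).append(og)
    out: dict[str, list[str]] = {}
    dropped = []
    for name, members in sets.sets.items():
        ogs: list[str] = []
        seen: set[str] = set()
        for sym in members:
            for og in symbol_to_ogs.get(sym.casefold(), ()):
                if og not in seen:
                    seen.add(og)
                    ogs.append(og)
        if ogs:
            out[name] = ogs
        else:
            dropped.append(name)
    if dropped:
        warnings.warn(
            f"{len(dropped)} gene set(s) had no mapped orthogroups and were "
            f"dropped: {dropped[:5]}{'...' if len(dropped) > 5 else ''}",
            UserWarning,
            stacklevel=2,
        )
    return out


def aggregate_set_counts(
    M: CopyNumberMatrix, mapping: dict[str, list[str]], set_name: str
) -> pd.Series:
    """Per-species aggregate copy number of a mapped gene set (each
    orthogroup counted once regardless of multiple annotations)."""
    if set_name not in mapping or not mapping[set_name]:
        raise KeyError(f"set {set_name!r} has no mapped orthogroups")
    ogs = list(dict.fromkeys(mapping[set_name]))
    agg = M.counts.loc[ogs].sum(axis=0)
    agg.name = set_name
    return agg


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------


def derive_cancer_phenotypes(raw: pd.DataFrame) -> PhenotypeTable:
    """Derive cancer phenotypes and weights from raw necropsy counts.

    neoplasia_prevalence  = n_neoplasia / n_necropsies
    malignancy_prevalence = n_malignant / n_necropsies
    malignancy_rate       = n_malignant / n_neoplasia  (NaN when no neoplasm)
    weight                = sqrt(n_necropsies)
    """
    df = raw.copy()
    missing = [c for c in PHENOTYPE_RAW_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"phenotype table missing columns: {missing}")
    for col in ("n_necropsies", "n_neoplasia", "n_malignant"):
        vals = df[col].to_numpy(dtype=float)
        if np.any(vals < 0) or np.any(vals != np.round(vals)):
            raise ValueError(f"{col} must hold non-negative integers")
    if (df["n_neoplasia"] > df["n_necropsies"]).any():
        bad = df.index[df["n_neoplasia"] > df["n_necropsies"]].tolist()
        raise ValueError(f"n_neoplasia exceeds n_necropsies for: {bad}")
    if (df["n_malignant"] > df["n_neoplasia"]).any():
        bad = df.index[df["n_malignant"] > df["n_neoplasia"]].tolist()
        raise ValueError(f"n_malignant exceeds n_neoplasia for: {bad}")
    if (df["n_necropsies"] <= 0).any():
        bad = df.index[df["n_necropsies"] <= 0].tolist()
        raise ValueError(f"n_necropsies must be positive; zero for: {bad}")
    df["neoplasia_prevalence"] = df["n_neoplasia"] / df["n_necropsies"]
    df["malignancy_prevalence"] = df["n_malignant"] / df["n_necropsies"]
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = df["n_malignant"] / df["n_neoplasia"]
    df["malignancy_rate"] = rate.where(df["n_neoplasia"] > 0)
    df["weight"] = np.sqrt(df["n_necropsies"].astype(float))
    return PhenotypeTable(table=df)


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    """Read a raw phenotype TSV (species + raw columns) and derive the
    cancer phenotypes."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return derive_cancer_phenotypes(df)


def write_phenotypes(pheno: PhenotypeTable, path: str | Path) -> None:
    pheno.table[list(PHENOTYPE_RAW_COLUMNS)].to_csv(
        path, sep="\t", index_label="species"
    )


def proteome_covariate(M: CopyNumberMatrix, mode: str = "all") -> pd.Series:
    """Per-species proteome-size proxy used as a model covariate.

    ``mode="all"`` sums counts over every orthogroup; ``"mouse_annotated"``
    restricts to orthogroups with a nonempty reference annotation (the
    covariate used alongside gene-set aggregates).
    """
    if mode not in ("all", "mouse_annotated"):
        raise ValueError(f"mode must be 'all' or 'mouse_annotated', got {mode!r}")
    if mode == "all":
        out = M.counts.sum(axis=0)
    else:
        annotated = [
            og for og in M.counts.index if M.annotation.get(og)
        ]
        if not annotated:
            warnings.warn(
                "no annotated orthogroups; mouse_annotated covariate is all "
                "zeros",
                UserWarning,
                stacklevel=2,
            )
            out = pd.Series(0, index=M.counts.columns)
        else:
            out = M.counts.loc[annotated].sum(axis=0)
    out.name = f"proteome_{mode}"
    return out
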