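"""Core in-memory containers shared across the pipeline stages.

The central object is :class:`AbundanceMatrix`: a proteins x samples table of
linear-scale abundances with an explicit missing-value mask, per-sample
metadata (condition, day, biological and technical repeat) and a provenance
log of the transforms applied to it.  Stages append to the provenance log so a
recorded run can always be traced.
"""

from __future__ import annotations

import dataclasses
import io
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

META_COLUMNS = ("sample_id", "condition", "day", "bio_rep", "tech_rep")
CONDITIONS = ("healthy", "disease")


def validate_meta(meta: pd.DataFrame) -> pd.DataFrame:
    """Check a sample-metadata table and return it indexed by sample_id."""
    missing = [c for c in META_COLUMNS if c not in meta.columns and c != meta.index.name]
    if meta.index.name != "sample_id" and "sample_id" in meta.columns:
        meta = meta.set_index("sample_id")
        missing = [c for c in META_COLUMNS[1:] if c not in meta.columns]
    if missing:
        raise ValueError(f"sample metadata is missing columns: {missing}")
    bad = set(meta["condition"]) - set(CONDITIONS)
    if bad:
        raise ValueError(f"unknown conditions in metadata: {sorted(bad)}")
    return meta


@dataclasses.dataclass
class AbundanceMatrix:
    """Proteins x samples abundance grid with metadata and provenance.

    ``values`` holds linear-scale abundances unless a transform noted in
    ``log`` says otherwise.  ``mask`` is True where the entry is missing;
    masked entries of ``values`` are NaN.
    """

    values: pd.DataFrame
    meta: pd.DataFrame
    mask: pd.DataFrame | None = None
    log: list[str] = dataclasses.field(default_factory=list)
    flags: dict[str, list[str]] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.meta = validate_meta(self.meta)
        if self.mask is None:
            self.mask = self.values.isna()
        if list(self.mask.index) != list(self.values.index) or list(
            self.mask.columns
        ) != list(self.values.columns):
            raise ValueError("mask must be aligned with values")
        extra = set(self.values.columns) - set(self.meta.index)
        if extra:
            raise ValueError(f"samples without metadata: {sorted(extra)[:5]}")

    # -- convenience -------------------------------------------------------
    @property
    def proteins(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def n_missing(self) -> int:
        return int(self.mask.to_numpy().sum())

    def copy(self) -> "AbundanceMatrix":
        return AbundanceMatrix(
            self.values.copy(),
            self.meta.copy(),
            self.mask.copy(),
            list(self.log),
            {k: list(v) for k, v in self.flags.items()},
        )

    def select_samples(self, sample_ids: Iterable[str]) -> "AbundanceMatrix":
        ids = list(sample_ids)
        return AbundanceMatrix(
            self.values[ids],
            self.meta.loc[ids],
            self.mask[ids],
            list(self.log) + [f"select_samples:{len(ids)}"],
            {k: list(v) for k, v in self.flags.items()},
        )

    # -- I/O ---------------------------------------------------------------
    def to_tsv(self, matrix_path: str | Path, meta_path: str | Path) -> None:
        self.values.rename_axis("protein_id").to_csv(matrix_path, sep="\t")
        self.meta.reset_index().to_csv(meta_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, matrix_path: str | Path, meta_path: str | Path) -> "AbundanceMatrix":
        values = pd.read_csv(matrix_path, sep="\t", index_col=0)
        meta = pd.read_csv(meta_path, sep="\t")
        return cls(values, meta)

    def serialise(self) -> bytes:
        """Canonical byte serialisation used for determinism checks."""
        buf = io.StringIO()
        self.values.rename_axis("protein_id").to_csv(buf, sep="\t", float_format="%.12g")
        self.meta.reset_index().to_csv(buf, sep="\t", index=False)
        return buf.getvalue().encode()


@dataclasses.dataclass
class PeptideTable:
    """Long-format peptide intensities: one row per (protein, peptide, sample)."""

    records: pd.DataFrame  # columns: protein_id, peptide_id, sample_id, intensity
    meta: pd.DataFrame

    REQUIRED = ("protein_id", "peptide_id", "sample_id", "intensity")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.records.columns]
        if missing:
            raise ValueError(f"peptide table missing columns: {missing}")
        if (self.records["intensity"] < 0).any():
            raise ValueError("peptide intensities must be non-negative")
        dup = self.records.duplicated(subset=["protein_id", "peptide_id", "sample_id"])
        if dup.any():
            raise ValueError("duplicate (protein, peptide, sample) rows")
        self.meta = validate_meta(self.meta)

    def to_tsv(self, path: str | Path) -> None:
        self.records.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, meta_path: str | Path) -> "PeptideTable":
        return cls(pd.read_csv(path, sep="\t"), pd.read_csv(meta_path, sep="\t"))


@dataclasses.dataclass
class AnnotationCollection:
    """Term -> protein-set annotations over a background universe."""

    terms: dict[str, set[str]]
    names: dict[str, str]
    universe: set[str]

    def restrict_to_universe(self, universe: Iterable[str]) -> "AnnotationCollection":
        uni = set(universe)
        terms = {t: s & uni for t, s in self.terms.items()}
        terms = {t: s for t, s in terms.items() if s}
        return AnnotationCollection(terms, {t: self.names.get(t, t) for t in terms}, uni)

    def write_gmt(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for term in sorted(self.terms):
                members = "\t".join(sorted(self.terms[term]))
                fh.write(f"{term}\t{self.names.get(term, term)}\t{members}\n")

    @classmethod
    def read_gmt(cls, path: str | Path, universe: Iterable[str] | None = None) -> "AnnotationCollection":
        terms: dict[str, set[str]] = {}
        names: dict[str, str] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 3:
                    raise ValueError(f"{path}: malformed GMT line {lineno}")
                term, name, *members = parts
                terms[term] = set(members)
                names[term] = name
        if universe is None:
            universe = set().union(*terms.values()) if terms else set()
        return cls(terms, names, set(universe))


def derive_seed(root_seed: int, component: str, index: int = 0) -> np.random.Generator:
    """Derive a component RNG from a single root seed.

    A stable per-component key keeps every stochastic stage independently
    reproducible from one recorded root seed.
    """
    key = sum(ord(c) * (31**i) for i, c in enumerate(component)) % (2**31)
    ss = np.random.SeedSequence(entropy=int(root_seed) % (2**31), spawn_key=(key, index))
    return np.random.default_rng(ss)
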