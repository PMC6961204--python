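"""Neutral-control selection for X-linked missense variants.

A presumed-neutral control for a pathogenic missense variant on an
X-chromosomal gene should (i) have been observed in at least one
hemizygous male — a male carrying a deleterious X-linked allele would be
expected to show a phenotype, so male-observed population variants are
unlikely to be disease-causing; (ii) be a physicochemically conservative
substitution; and (iii) ideally co-locate with the pathogenic sites, here
in the same repeat unit of the TPR solenoid.

Substitution conservativeness is scored as the fraction of shared binary
physicochemical properties (a Taylor/Zvelebil-style 10-property
classification).  The property table ships as an editable data file, not
code.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .io import RepeatAnnotation

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")

#: Conserved consensus positions of the extended OGT-type TPR repeat
#: (N6-L7-G8-G15-A20-Y24-A27-Ψ30-P32); other repeat positions count as
#: unconserved when labelling variants.
OGT_CONSENSUS_POSITIONS = frozenset({6, 7, 8, 15, 20, 24, 27, 30, 32})


@dataclass
class PropertyTable:
    """Binary physicochemical property vectors for the 20 standard residues."""

    properties: tuple[str, ...]
    vectors: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        missing = STANDARD_AA - set(self.vectors)
        if missing:
            raise ValueError(f"property table missing residues: {sorted(missing)}")
        n = len(self.properties)
        for aa, vec in self.vectors.items():
            if len(vec) != n:
                raise ValueError(f"{aa}: vector length {len(vec)} != {n}")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PropertyTable":
        df = pd.read_csv(path, sep="\t")
        props = tuple(c for c in df.columns if c != "aa")
        vectors = {row["aa"]: np.array([int(row[p]) for p in props])
                   for _, row in df.iterrows()}
        return cls(properties=props, vectors=vectors)

    @classmethod
    def default(cls) -> "PropertyTable":
        return cls.from_tsv(Path(__file__).parent / "data" / "residue_properties.tsv")


@dataclass
class VariantRecord:
    """One missense record in the style of a population variant database."""

    position: int            # protein residue number
    wt: str                  # one-letter wild-type residue
    alt: str                 # one-letter substituted residue
    ac_total: int            # allele count, all individuals
    ac_male: int             # allele count in males (hemizygous carriers)
    unit: str | None = None  # repeat unit, filled from the annotation
    consensus: str = "unconserved"  # consensus position label or "unconserved"
    pathogenic: bool = False

    def __post_init__(self) -> None:
        if self.wt not in STANDARD_AA or self.alt not in STANDARD_AA:
            raise ValueError(
                f"non-standard residue in {self.wt}{self.position}{self.alt}")
        if self.ac_total < 0 or self.ac_male < 0:
            raise ValueError("allele counts must be non-negative")
        if self.ac_male > self.ac_total:
            raise ValueError(
                f"{self.label}: male count {self.ac_male} exceeds total {self.ac_total}")

    @property
    def label(self) -> str:
        return f"{self.wt}{self.position}{self.alt}"


def read_variants_tsv(path: str | Path) -> list[VariantRecord]:
    """Read variants from TSV with columns pos, wt, alt, ac_total, ac_male."""
    df = pd.read_csv(path, sep="\t")
    required = ["pos", "wt", "alt", "ac_total", "ac_male"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    return [VariantRecord(position=int(r.pos), wt=str(r.wt), alt=str(r.alt),
                          ac_total=int(r.ac_total), ac_male=int(r.ac_male))
            for r in df.itertuples()]


def annotate_variants(variants: list[VariantRecord], ann: RepeatAnnotation,
                      conserved_positions: frozenset = OGT_CONSENSUS_POSITIONS
                      ) -> list[VariantRecord]:
    """Fill each record's repeat unit and consensus-position label.

    A residue is labelled Ψp only when its repeat position p belongs to
    ``conserved_positions``; all other positions are "unconserved".
    """
    out = []
    for v in variants:
        unit = ann.unit_of_residue(v.position)
        psi = ann.consensus_position(v.position)
        conserved = psi is not None and psi in conserved_positions
        out.append(replace(v, unit=unit,
                           consensus=f"Ψ{psi}" if conserved else "unconserved"))
    return out


def filter_male_observed(variants: list[VariantRecord]) -> list[VariantRecord]:
    """Keep variants observed in at least one male, preserving order.

    For an X-linked gene these are the strongest neutral-control
    candidates: a male carries a single allele, so an observed healthy
    male carrier argues against pathogenicity.
    """
    return [v for v in variants if v.ac_male >= 1]


def conservation_score(wt: str, alt: str,
                       table: PropertyTable | None = None) -> float:
    """Fraction of binary physicochemical properties shared by wt and alt.

    A property counts as shared when it is present in both or absent in
    both residues; the score is symmetric and equals 1 iff the property
    vectors are identical.
    """
    table = table or PropertyTable.default()
    for aa in (wt, alt):
        if aa not in table.vectors:
            raise ValueError(f"unknown residue {aa!r}")
    a, b = table.vectors[wt], table.vectors[alt]
    return float(np.mean(a == b))


def rank_controls(variants: list[VariantRecord], ann: RepeatAnnotation,
                  pathogenic_sites: list[int],
                  table: PropertyTable | None = None) -> pd.DataFrame:
    """Rank control candidates by co-location, conservativeness and frequency.

    Sort keys, in order: (1) residing in a repeat unit that contains a
    known pathogenic site, (2) conservation score descending, (3) total
    allele count descending; ties keep the stable input order.  Returns a
    DataFrame with the full score breakdown; ranking is a permutation of
    the input (no records created or dropped).
    """
    table = table or PropertyTable.default()
    pathogenic_units = {ann.unit_of_residue(p) for p in pathogenic_sites}
    pathogenic_units.discard(None)
    rows = []
    for i, v in enumerate(variants):
        unit = v.unit if v.unit is not None else ann.unit_of_residue(v.position)
        rows.append({
            "variant": v.label, "pos": v.position, "wt": v.wt, "alt": v.alt,
            "unit": unit if unit is not None else "",
            "consensus": v.consensus,
            "ac_total": v.ac_total, "ac_male": v.ac_male,
            "co_located": unit in pathogenic_units,
            "conservation": conservation_score(v.wt, v.alt, table),
            "_input_order": i,
        })
    df = pd.DataFrame(rows)
    df = df.sort_values(
        by=["co_located", "conservation", "ac_total", "_input_order"],
        ascending=[False, False, False, True], kind="stable")
    df = df.drop(columns="_input_order").reset_index(drop=True)
    df.index.name = "rank"
    return df
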