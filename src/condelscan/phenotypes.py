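"""Species phenotype/clade table driving all genotype-phenotype counting.

Each species is either the single ``reference`` assembly, an ``outgroup``
(trait-complete), or a ``target`` (member of a trait-reduced lineage).
Targets carry a clade id; clades with two or more members are "screened"
clades whose per-base deletion quorum gates candidacy, while singleton
lineages are soft evidence only (reported, never gating).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import pandas as pd

__all__ = ["PhenotypeMatrix", "read_phenotypes", "parse_phenotypes_text"]

_ROLES = ("reference", "outgroup", "target")


@dataclass(frozen=True)
class PhenotypeMatrix:
    reference: str
    outgroups: tuple[str, ...]
    targets: tuple[str, ...]
    clade_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sp in self.targets:
            if sp not in self.clade_of:
                raise ValueError(f"target {sp!r} has no clade_id")
        names = [self.reference, *self.outgroups, *self.targets]
        if len(set(names)) != len(names):
            raise ValueError("duplicate species_id in phenotype matrix")

    @property
    def species(self) -> tuple[str, ...]:
        return (self.reference, *self.outgroups, *self.targets)

    def clade_members(self, clade_id: str) -> tuple[str, ...]:
        return tuple(sp for sp in self.targets
                     if self.clade_of[sp] == clade_id)

    @property
    def clades(self) -> tuple[str, ...]:
        seen: list[str] = []
        for sp in self.targets:
            c = self.clade_of[sp]
            if c not in seen:
                seen.append(c)
        return tuple(seen)

    def screened_clades(self, min_members: int = 2) -> tuple[str, ...]:
        """Clades large enough to carry a deletion quorum on their own."""
        return tuple(c for c in self.clades
                     if len(self.clade_members(c)) >= min_members)


def parse_phenotypes_text(text: str) -> PhenotypeMatrix:
    df = pd.read_csv(io.StringIO(text), sep="\t", dtype=str,
                     comment="#").fillna("")
    required = {"species_id", "role"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"phenotype table needs columns {sorted(required)}, "
            f"got {list(df.columns)}")
    bad = set(df["role"]) - set(_ROLES)
    if bad:
        raise ValueError(f"unknown role(s) {sorted(bad)}; expected {_ROLES}")
    refs = df.loc[df["role"] == "reference", "species_id"].tolist()
    if len(refs) != 1:
        raise ValueError(
            f"exactly one reference species required, found {len(refs)}")
    outgroups = tuple(df.loc[df["role"] == "outgroup", "species_id"])
    tdf = df[df["role"] == "target"]
    targets = tuple(tdf["species_id"])
    if "clade_id" not in df.columns and len(targets):
        raise ValueError("target species present but no clade_id column")
    clade_of = {}
    for _, row in tdf.iterrows():
        clade = row.get("clade_id", "")
        if not clade:
            raise ValueError(f"target {row['species_id']!r} has no clade_id")
        clade_of[row["species_id"]] = clade
    return PhenotypeMatrix(refs[0], outgroups, targets, clade_of)


def read_phenotypes(path) -> PhenotypeMatrix:
    with open(path, encoding="utf-8") as fh:
        return parse_phenotypes_text(fh.read())


def write_phenotypes_text(matrix: PhenotypeMatrix) -> str:
    lines = ["species_id\trole\tclade_id\tnotes"]
    lines.append(f"{matrix.reference}\treference\t\t")
    for sp in matrix.outgroups:
        lines.append(f"{sp}\toutgroup\t\t")
    for sp in matrix.targets:
        lines.append(f"{sp}\ttarget\t{matrix.clade_of[sp]}\t")
    return "\n".join(lines) + "\n"
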