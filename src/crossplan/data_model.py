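"""Domain types and file I/O for genotypes, genetic maps, effects and mating designs.

Conventions used throughout the package:

* Allele doses count the ALT (second) allele and live in {0, 1, 2}. Fully
  inbred material carries only 0/2; a dose of 1 is permitted only for
  simulated segregating progeny (e.g. residually heterozygous F5 RILs).
* Genetic map positions are in morgans, non-decreasing within a chromosome.
* A candidate cross is an unordered pair of parents, canonically stored with
  ``parent_i < parent_j`` in id sort order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "GeneticMap",
    "TraitArchitecture",
    "EffectVector",
    "MatingDesign",
    "ConstraintSet",
    "read_genotypes",
    "read_map",
    "read_effects",
    "read_design",
    "write_design",
    "compute_breeding_values",
    "canonical_pair",
]


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Return the unordered pair (a, b) in canonical (sorted) order."""
    if a == b:
        raise ValueError(f"self-cross is not a valid pair: {a!r}")
    return (a, b) if a < b else (b, a)


@dataclass
class GenotypeMatrix:
    """Individuals x loci allele-dose matrix.

    Parameters
    ----------
    ids : individual identifiers (length n).
    doses : (n, L) integer array with values in {0, 1, 2}.
    locus_ids : locus identifiers (length L), keys into a :class:`GeneticMap`.
    allow_het : whether dose 1 is permitted (simulated segregating material).
    """

    ids: list[str]
    doses: np.ndarray
    locus_ids: list[str]
    allow_het: bool = False

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses)
        if self.doses.ndim != 2:
            raise ValueError("doses must be a 2-D array")
        if self.doses.shape != (len(self.ids), len(self.locus_ids)):
            raise ValueError(
                f"doses shape {self.doses.shape} does not match "
                f"{len(self.ids)} individuals x {len(self.locus_ids)} loci"
            )
        bad = ~np.isin(self.doses, (0, 1, 2))
        if bad.any():
            i, l = np.argwhere(bad)[0]
            raise ValueError(
                f"dose outside {{0,1,2}} for individual {self.ids[i]!r} "
                f"at locus {self.locus_ids[l]!r}: {self.doses[i, l]!r}"
            )
        if not self.allow_het:
            het = self.doses == 1
            if het.any():
                i, l = np.argwhere(het)[0]
                raise ValueError(
                    f"heterozygous call (dose 1) in inbred material: "
                    f"individual {self.ids[i]!r}, locus {self.locus_ids[l]!r}"
                )

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    def allele_frequencies(self) -> np.ndarray:
        """Frequency of the counted allele per locus (mean dose / 2)."""
        return self.doses.mean(axis=0) / 2.0

    def row(self, individual: str) -> np.ndarray:
        try:
            return self.doses[self.ids.index(individual)]
        except ValueError as exc:
            raise KeyError(f"unknown individual {individual!r}") from exc

    def subset_loci(self, locus_ids: Sequence[str]) -> "GenotypeMatrix":
        index = {l: k for k, l in enumerate(self.locus_ids)}
        missing = [l for l in locus_ids if l not in index]
        if missing:
            raise KeyError(f"loci absent from genotype matrix: {missing[:5]}")
        cols = [index[l] for l in locus_ids]
        return GenotypeMatrix(
            list(self.ids), self.doses[:, cols], list(locus_ids), self.allow_het
        )

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.doses, index=self.ids, columns=self.locus_ids)
        df.index.name = "id"
        df.to_csv(path, sep="\t")


@dataclass
class GeneticMap:
    """Per-locus chromosome and genetic position (morgans).

    ``table`` has columns chrom, locus_id, pos_morgans and optionally arm
    ({short, centromere, long}); rows sorted by (chrom, pos_morgans, locus_id).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"chrom", "locus_id", "pos_morgans"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"map requires columns {sorted(required)}")
        if self.table["locus_id"].duplicated().any():
            dup = self.table.loc[self.table["locus_id"].duplicated(), "locus_id"].iloc[0]
            raise ValueError(f"duplicate locus id in map: {dup!r}")
        for chrom, grp in self.table.groupby("chrom", sort=False):
            pos = grp["pos_morgans"].to_numpy(float)
            if np.any(np.diff(pos) < 0):
                raise ValueError(f"map positions decrease within chromosome {chrom!r}")
        self.table = self.table.reset_index(drop=True)

    @property
    def locus_ids(self) -> list[str]:
        return self.table["locus_id"].tolist()

    @property
    def chromosomes(self) -> list:
        seen: dict = {}
        for c in self.table["chrom"]:
            seen.setdefault(c, None)
        return list(seen)

    def positions(self, chrom) -> np.ndarray:
        return self.table.loc[self.table["chrom"] == chrom, "pos_morgans"].to_numpy(float)

    def chrom_slices(self) -> dict:
        """Map chromosome -> integer index array into the locus order."""
        out = {}
        for chrom, grp in self.table.groupby("chrom", sort=False):
            out[chrom] = grp.index.to_numpy()
        return out

    def arms(self) -> pd.Series:
        """Block labels per locus; defaults to the middle 20% of each
        chromosome as the centromere block when no ``arm`` column is given."""
        if "arm" in self.table.columns and self.table["arm"].notna().all():
            return self.table["arm"]
        labels = np.empty(len(self.table), dtype=object)
        for chrom, grp in self.table.groupby("chrom", sort=False):
            pos = grp["pos_morgans"].to_numpy(float)
            lo, hi = pos.min(), pos.max()
            span = hi - lo if hi > lo else 1.0
            rel = (pos - lo) / span
            lab = np.where(rel < 0.4, "short", np.where(rel <= 0.6, "centromere", "long"))
            labels[grp.index.to_numpy()] = lab
        return pd.Series(labels, index=self.table.index, name="arm")

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass
class EffectVector:
    """Additive allele-substitution effects per locus.

    ``scope`` records whether the effects are true QTL effects
    (``qtl_only``) or estimated marker effects with QTL genotypes removed
    (``markers_excluding_qtl``).
    """

    locus_ids: list[str]
    values: np.ndarray
    scope: str = "qtl_only"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.locus_ids) != self.values.size:
            raise ValueError("effects length does not match locus ids")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite effect values")

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame({"locus_id": self.locus_ids, "beta": self.values}).to_csv(
            path, sep="\t", index=False
        )


@dataclass
class TraitArchitecture:
    """QTL subset of the map plus additive effects defining the TBV."""

    qtl_ids: list[str]
    beta: np.ndarray

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if len(self.qtl_ids) != self.beta.size:
            raise ValueError("beta length does not match QTL ids")
        if len(set(self.qtl_ids)) != len(self.qtl_ids):
            raise ValueError("duplicate QTL ids")

    def effects(self) -> EffectVector:
        return EffectVector(list(self.qtl_ids), self.beta.copy(), scope="qtl_only")


@dataclass
class MatingDesign:
    """Allocation of progeny counts to selected crosses."""

    crosses: list[tuple[str, str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = set()
        canon = []
        for a, b, d in self.crosses:
            a, b = canonical_pair(a, b)
            if (a, b) in seen:
                raise ValueError(f"duplicate cross {a}x{b}")
            d = int(d)
            if d <= 0:
                raise ValueError(f"non-positive progeny count for {a}x{b}: {d}")
            seen.add((a, b))
            canon.append((a, b, d))
        self.crosses = canon

    @property
    def total_progeny(self) -> int:
        return sum(d for _, _, d in self.crosses)

    @property
    def n_crosses(self) -> int:
        return len(self.crosses)

    def parents(self) -> list[str]:
        out: dict = {}
        for a, b, _ in self.crosses:
            out.setdefault(a, None)
            out.setdefault(b, None)
        return sorted(out)

    def allocation(self) -> dict[tuple[str, str], int]:
        return {(a, b): d for a, b, d in self.crosses}


@dataclass
class ConstraintSet:
    """Mating-design constraints on progeny totals and parental contributions.

    Defaults follow elite bread-wheat practice: 3,300 progeny in total, 5-60
    per cross, 200-300 crosses, at most 250 progeny per parent, 100-132
    recruited parents, and exclusion of parent pairs above the 99% quantile
    of pairwise genomic covariance.
    """

    D_total: int = 3300
    D_min: int = 5
    D_max: int = 60
    K_min: int = 200
    K_max: int = 300
    C_max: int = 250
    P_min: int = 100
    P_max: int = 132
    similarity_quantile: float = 0.99

    def __post_init__(self) -> None:
        if self.D_min > self.D_max:
            raise ValueError("D_min > D_max")
        if self.K_min > self.K_max:
            raise ValueError("K_min > K_max")
        if self.P_min > self.P_max:
            raise ValueError("P_min > P_max")
        if not (0.0 < self.similarity_quantile <= 1.0):
            raise ValueError("similarity_quantile must be in (0, 1]")
        if self.K_min * self.D_min > self.D_total:
            raise ValueError("infeasible: K_min * D_min exceeds D_total")
        if self.K_max * self.D_max < self.D_total:
            raise ValueError("infeasible: K_max * D_max below D_total")


# ---------------------------------------------------------------------------
# file I/O


def read_genotypes(path: str | Path, format: str = "dose_tsv") -> GenotypeMatrix:
    """Read inbred-line genotypes from a dose TSV or a biallelic VCF.

    Dose TSV: rows = individuals (first column ``id``), columns = loci,
    values in {0, 1, 2}. VCF: requires cyvcf2; each record must be biallelic
    and every genotype homozygous (founder panels are fully inbred).
    """
    if format == "dose_tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        doses = df.to_numpy()
        allow_het = bool((doses == 1).any())
        return GenotypeMatrix(
            [str(i) for i in df.index], doses.astype(np.int8),
            [str(c) for c in df.columns], allow_het=allow_het,
        )
    if format == "vcf":
        return _read_vcf(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_vcf(path: str | Path) -> GenotypeMatrix:
    from cyvcf2 import VCF  # optional dependency

    vcf = VCF(str(path))
    ids = list(vcf.samples)
    locus_ids: list[str] = []
    rows = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise ValueError(f"multiallelic site {rec.ID or rec.CHROM + ':' + str(rec.POS)}")
        gts = np.asarray(rec.gt_types)  # 0=hom ref, 1=het, 2=unknown, 3=hom alt
        if (gts == 1).any():
            who = ids[int(np.argmax(gts == 1))]
            site = rec.ID or f"{rec.CHROM}:{rec.POS}"
            raise ValueError(f"heterozygous founder call for {who!r} at {site}")
        if (gts == 2).any():
            who = ids[int(np.argmax(gts == 2))]
            site = rec.ID or f"{rec.CHROM}:{rec.POS}"
            raise ValueError(f"missing genotype for {who!r} at {site}")
        rows.append(np.where(gts == 3, 2, 0).astype(np.int8))
        locus_ids.append(rec.ID or f"{rec.CHROM}:{rec.POS}")
    doses = np.column_stack(rows) if rows else np.zeros((len(ids), 0), dtype=np.int8)
    return GenotypeMatrix(ids, doses, locus_ids)


def read_map(path: str | Path) -> GeneticMap:
    df = pd.read_csv(path, sep="\t")
    df["locus_id"] = df["locus_id"].astype(str)
    return GeneticMap(df)


def read_effects(path: str | Path, scope: str = "qtl_only") -> EffectVector:
    df = pd.read_csv(path, sep="\t")
    return EffectVector(
        [str(l) for l in df["locus_id"]], df["beta"].to_numpy(float), scope=scope
    )


def write_design(design: MatingDesign, path: str | Path) -> None:
    """Write a design CSV (parent_i, parent_j, n_progeny) sorted by
    descending progeny count, pair id as tie-break."""
    rows = sorted(design.crosses, key=lambda c: (-c[2], c[0], c[1]))
    pd.DataFrame(rows, columns=["parent_i", "parent_j", "n_progeny"]).to_csv(
        path, index=False
    )


def read_design(path: str | Path) -> MatingDesign:
    df = pd.read_csv(path)
    return MatingDesign(
        [(str(a), str(b), int(d)) for a, b, d in
         zip(df["parent_i"], df["parent_j"], df["n_progeny"])]
    )


# ---------------------------------------------------------------------------
# breeding values


def compute_breeding_values(
    genotypes: GenotypeMatrix, effects: EffectVector
) -> np.ndarray:
    """Breeding values as the cross product of allele doses and effects.

    value_i = sum_l dose_il * beta_l over the loci named by ``effects``.
    """
    sub = genotypes.subset_loci(effects.locus_ids)
    return sub.doses @ effects.values
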