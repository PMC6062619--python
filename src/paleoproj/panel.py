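"""Allele-frequency panel and genotype data model, with marker harmonization.

The reference panel is a table of biallelic SNPs with one counted-allele
frequency column per ancestry.  Target genotypes come from VCF; before
projection the two marker sets are intersected on (chrom, pos) and the VCF
dosages are re-oriented so that they count the panel's counted allele.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DIPLOID = "diploid"
PSEUDO_HAPLOID = "pseudo_haploid"

_VALID_BASES = frozenset("ACGT")
#: allele pairs that are their own reverse complement and therefore cannot be
#: strand-checked (A/T and C/G)
_AMBIGUOUS_PAIRS = frozenset({frozenset("AT"), frozenset("CG")})

PANEL_META_COLUMNS = ["id", "chrom", "pos", "counted_allele", "other_allele"]


class PanelParseError(ValueError):
    """Raised for malformed panel or haplogroup input files."""


class AlignmentError(ValueError):
    """Raised when genotypes cannot be harmonized with the panel."""


@dataclass(frozen=True)
class Marker:
    """A biallelic SNP with an explicit counted allele."""

    id: str
    chrom: str
    pos: int
    counted_allele: str
    other_allele: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"marker {self.id}: position must be >= 1, got {self.pos}")
        for allele in (self.counted_allele, self.other_allele):
            if allele not in _VALID_BASES:
                raise ValueError(f"marker {self.id}: allele {allele!r} not in A/C/G/T")
        if self.counted_allele == self.other_allele:
            raise ValueError(f"marker {self.id}: counted and other allele are identical")

    @property
    def is_strand_ambiguous(self) -> bool:
        return frozenset((self.counted_allele, self.other_allele)) in _AMBIGUOUS_PAIRS


@dataclass
class FrequencyPanel:
    """Ancestry-specific counted-allele frequencies, K ancestries x M markers."""

    markers: list[Marker]
    ancestries: list[str]
    freqs: np.ndarray  # shape (K, M), values in [0, 1]

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        K, M = len(self.ancestries), len(self.markers)
        if K < 1 or M < 1:
            raise ValueError("panel needs at least one ancestry and one marker")
        if self.freqs.shape != (K, M):
            raise ValueError(
                f"frequency matrix shape {self.freqs.shape} != (K={K}, M={M})"
            )
        if len(set(self.ancestries)) != K:
            raise ValueError("ancestry labels must be unique")
        ids = [m.id for m in self.markers]
        if len(set(ids)) != M:
            raise ValueError("duplicate marker ids in panel")
        if np.any(self.freqs < 0) or np.any(self.freqs > 1):
            raise ValueError("panel frequencies must lie in [0, 1]")

    @property
    def n_ancestries(self) -> int:
        return len(self.ancestries)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def restrict(self, index: np.ndarray) -> "FrequencyPanel":
        """Panel restricted to the given marker indices, in the given order."""
        return FrequencyPanel(
            markers=[self.markers[i] for i in index],
            ancestries=list(self.ancestries),
            freqs=self.freqs[:, index].copy(),
        )

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(
            {
                "id": [m.id for m in self.markers],
                "chrom": [m.chrom for m in self.markers],
                "pos": [m.pos for m in self.markers],
                "counted_allele": [m.counted_allele for m in self.markers],
                "other_allele": [m.other_allele for m in self.markers],
            }
        )
        for k, label in enumerate(self.ancestries):
            df[label] = self.freqs[k]
        df.to_csv(path, sep="\t", index=False, float_format="%.6f")


@dataclass
class GenotypeMatrix:
    """Counted-allele dosages for N individuals at M markers.

    Dosages are floats in {0, 1, 2} with NaN for missing calls.  Individuals
    flagged pseudo-haploid carry a single sampled allele coded {0, 2}.
    """

    individuals: list[str]
    markers: list[Marker]
    dosages: np.ndarray  # shape (N, M)
    ploidy: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        N, M = len(self.individuals), len(self.markers)
        if self.dosages.shape != (N, M):
            raise ValueError(f"dosage shape {self.dosages.shape} != (N={N}, M={M})")
        if not self.ploidy:
            self.ploidy = [DIPLOID] * N
        if len(self.ploidy) != N:
            raise ValueError("ploidy flags must match number of individuals")
        finite = self.dosages[np.isfinite(self.dosages)]
        if finite.size and (np.any(finite < 0) or np.any(finite > 2)):
            raise ValueError("dosages must be in {0, 1, 2} or missing")
        for i, flag in enumerate(self.ploidy):
            if flag == PSEUDO_HAPLOID:
                row = self.dosages[i]
                obs = row[np.isfinite(row)]
                if np.any(obs == 1):
                    raise ValueError(
                        f"pseudo-haploid individual {self.individuals[i]} "
                        "has a heterozygous dosage"
                    )

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_markers(self) -> int:
        return len(self.markers)


@dataclass
class AlignedDataset:
    """Panel and genotypes restricted to shared, harmonized markers."""

    panel: FrequencyPanel
    genotypes: GenotypeMatrix
    alignment_report: dict[str, int]

    def __post_init__(self) -> None:
        pk = [(m.chrom, m.pos) for m in self.panel.markers]
        gk = [(m.chrom, m.pos) for m in self.genotypes.markers]
        if pk != gk:
            raise ValueError("aligned panel and genotypes must share marker order")


def read_frequency_panel(path) -> FrequencyPanel:
    """Read a tab-separated frequency panel.

    Expected header: id, chrom, pos, counted_allele, other_allele, then one
    frequency column per ancestry (column order defines ancestry order).
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype={"id": str, "chrom": str})
    except Exception as exc:  # noqa: BLE001 - wrap any parse failure
        raise PanelParseError(f"cannot parse panel file {path}: {exc}") from exc
    missing = [c for c in PANEL_META_COLUMNS if c not in df.columns]
    if missing:
        raise PanelParseError(f"panel file {path} lacks columns {missing}")
    ancestries = [c for c in df.columns if c not in PANEL_META_COLUMNS]
    if not ancestries:
        raise PanelParseError(f"panel file {path} has no ancestry columns")

    markers = []
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        try:
            markers.append(
                Marker(
                    id=str(row["id"]),
                    chrom=str(row["chrom"]),
                    pos=int(row["pos"]),
                    counted_allele=str(row["counted_allele"]),
                    other_allele=str(row["other_allele"]),
                )
            )
        except (ValueError, TypeError) as exc:
            raise PanelParseError(f"{path}, line {line}: {exc}") from exc

    freqs = df[ancestries].to_numpy(dtype=float).T
    bad = np.argwhere(~((freqs >= 0) & (freqs <= 1)))
    if bad.size:
        k, m = bad[0]
        raise PanelParseError(
            f"{path}, line {m + 2}: frequency {freqs[k, m]!r} for ancestry "
            f"{ancestries[k]!r} outside [0, 1]"
        )
    ids = pd.Index([m.id for m in markers])
    if ids.has_duplicates:
        dup = ids[ids.duplicated()][0]
        line = int(np.argmax(ids == dup)) + 2
        raise PanelParseError(f"{path}: duplicate marker id {dup!r} (first at line {line})")
    return FrequencyPanel(markers=markers, ancestries=ancestries, freqs=freqs)


def read_genotypes_vcf(path, pseudo_haploid: list[str] | None = None) -> GenotypeMatrix:
    """Read ALT-allele dosages from a VCF (plain or bgzipped).

    Multi-allelic and non-SNP records are skipped with a warning.  Haploid GT
    calls are coded {0, 2}; an individual whose non-missing calls are all
    haploid is flagged pseudo-haploid unless ``pseudo_haploid`` explicitly
    lists the individuals to flag.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path), gts012=False)
    except Exception as exc:  # noqa: BLE001
        raise OSError(f"cannot read VCF {path}: {exc}") from exc

    individuals = list(vcf.samples)
    n = len(individuals)
    markers: list[Marker] = []
    rows: list[np.ndarray] = []
    any_haploid = np.zeros(n, dtype=bool)
    any_diploid = np.zeros(n, dtype=bool)
    n_skipped = 0

    for variant in vcf:
        if len(variant.ALT) != 1:
            n_skipped += 1
            continue
        ref, alt = variant.REF, variant.ALT[0]
        if len(ref) != 1 or len(alt) != 1 or ref not in _VALID_BASES or alt not in _VALID_BASES:
            n_skipped += 1
            continue
        try:
            genotypes = variant.genotypes
        except Exception as exc:  # noqa: BLE001
            raise PanelParseError(
                f"{path}: record {variant.CHROM}:{variant.POS} has no readable GT"
            ) from exc
        if genotypes is None or len(genotypes) != n:
            raise PanelParseError(
                f"{path}: record {variant.CHROM}:{variant.POS} lacks a GT field"
            )
        dose = np.full(n, np.nan)
        for i, gt in enumerate(genotypes):
            alleles = list(gt[:-1])
            if any(a < 0 for a in alleles):  # "./." or partial call -> missing
                continue
            if len(alleles) == 1:
                dose[i] = 2.0 * alleles[0]
                any_haploid[i] = True
            else:
                dose[i] = float(sum(alleles))
                any_diploid[i] = True
        name = variant.ID if variant.ID not in (None, ".") else f"{variant.CHROM}:{variant.POS}"
        markers.append(
            Marker(id=name, chrom=variant.CHROM, pos=variant.POS,
                   counted_allele=alt, other_allele=ref)
        )
        rows.append(dose)
    vcf.close()

    if n_skipped:
        warnings.warn(
            f"{path}: skipped {n_skipped} multi-allelic or non-SNP record(s)",
            stacklevel=2,
        )
    if not markers:
        raise PanelParseError(f"{path}: no usable biallelic SNP records")

    if pseudo_haploid is None:
        ploidy = [
            PSEUDO_HAPLOID if any_haploid[i] and not any_diploid[i] else DIPLOID
            for i in range(n)
        ]
    else:
        unknown = set(pseudo_haploid) - set(individuals)
        if unknown:
            raise ValueError(f"pseudo-haploid override names unknown individuals: {unknown}")
        ploidy = [PSEUDO_HAPLOID if s in pseudo_haploid else DIPLOID for s in individuals]

    return GenotypeMatrix(
        individuals=individuals,
        markers=markers,
        dosages=np.vstack(rows).T,
        ploidy=ploidy,
    )


def complement_dosage(dosages: np.ndarray) -> np.ndarray:
    """Swap which allele is counted: dosage -> 2 - dosage, missing unchanged."""
    return 2.0 - np.asarray(dosages, dtype=float)


def align_genotypes_to_panel(gm: GenotypeMatrix, panel: FrequencyPanel) -> AlignedDataset:
    """Intersect markers on (chrom, pos) and harmonize the counted allele.

    For each shared site: if the VCF alleles match the panel's (counted,
    other) pair the dosage is kept; if they are the swap of that pair the
    dosage is complemented; strand-ambiguous pairs (A/T, C/G) and allele-set
    mismatches are dropped.  The report tallies each category.
    """
    panel_by_site = {(m.chrom, m.pos): i for i, m in enumerate(panel.markers)}
    report = {"kept": 0, "swapped": 0, "ambiguous_dropped": 0, "mismatch_dropped": 0}
    panel_idx: list[int] = []
    geno_idx: list[int] = []
    flip: list[bool] = []

    for j, gmark in enumerate(gm.markers):
        i = panel_by_site.get((gmark.chrom, gmark.pos))
        if i is None:
            continue
        pmark = panel.markers[i]
        if pmark.is_strand_ambiguous or gmark.is_strand_ambiguous:
            report["ambiguous_dropped"] += 1
            continue
        vcf_pair = (gmark.counted_allele, gmark.other_allele)
        if vcf_pair == (pmark.counted_allele, pmark.other_allele):
            report["kept"] += 1
            flipped = False
        elif vcf_pair == (pmark.other_allele, pmark.counted_allele):
            report["swapped"] += 1
            flipped = True
        else:
            report["mismatch_dropped"] += 1
            continue
        panel_idx.append(i)
        geno_idx.append(j)
        flip.append(flipped)

    n_intersect = sum(report.values())
    if not panel_idx:
        raise AlignmentError(
            f"no usable shared markers between genotypes and panel "
            f"(intersection size {n_intersect}); check that the marker sets "
            "use the same build and allele coding"
        )

    # order markers by panel order
    order = np.argsort(panel_idx, kind="stable")
    panel_idx_arr = np.asarray(panel_idx)[order]
    geno_idx_arr = np.asarray(geno_idx)[order]
    flip_arr = np.asarray(flip)[order]

    sub_panel = panel.restrict(panel_idx_arr)
    dos = gm.dosages[:, geno_idx_arr].copy()
    if flip_arr.any():
        dos[:, flip_arr] = complement_dosage(dos[:, flip_arr])
    aligned_gm = GenotypeMatrix(
        individuals=list(gm.individuals),
        markers=list(sub_panel.markers),
        dosages=dos,
        ploidy=list(gm.ploidy),
    )
    return AlignedDataset(panel=sub_panel, genotypes=aligned_gm, alignment_report=report)


def write_alignment_report(report: dict[str, int], path) -> None:
    with open(path, "w") as fh:
        for key, value in report.items():
            fh.write(f"{key}\t{value}\n")


def write_vcf(gm: GenotypeMatrix, path, swap_markers: set[str] | None = None) -> None:
    """Write dosages as a minimal VCF 4.2 file.

    ``swap_markers`` optionally names marker ids to emit with REF/ALT swapped
    (and dosages complemented), for allele-harmonization round trips.
    """
    swap_markers = swap_markers or set()
    contigs = sorted({m.chrom for m in gm.markers})
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=paleoproj-simulator\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(gm.individuals) + "\n")
        is_ph = [p == PSEUDO_HAPLOID for p in gm.ploidy]
        for j, m in enumerate(gm.markers):
            swap = m.id in swap_markers
            ref = m.counted_allele if swap else m.other_allele
            alt = m.other_allele if swap else m.counted_allele
            fields = [m.chrom, str(m.pos), m.id, ref, alt, ".", "PASS", ".", "GT"]
            for i in range(gm.n_individuals):
                d = gm.dosages[i, j]
                if not np.isfinite(d):
                    fields.append("." if is_ph[i] else "./.")
                    continue
                alt_count = int(round((2.0 - d) if swap else d))
                if is_ph[i]:
                    fields.append("1" if alt_count == 2 else "0")
                else:
                    fields.append({0: "0/0", 1: "0/1", 2: "1/1"}[alt_count])
            fh.write("\t".join(fields) + "\n")
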