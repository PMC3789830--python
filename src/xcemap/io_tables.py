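"""Tabular input/output for the Xce mapping and phenotyping pipeline.

Three input families are handled:

* genotype tables — variants x strains matrices of base calls for inbred
  mouse strains, with 1-based genomic coordinates (emulating high-density
  array and whole-genome-sequence calls);
* allele-specific expression tables — per-measurement maternal-allele
  fractions (pyrosequencing) or maternal/paternal read counts (RNA-seq) for
  F1 hybrid females;
* strain panels — the map from strain name to its known Xce allele, anchored
  to a reference strain (C57BL/6J by default).

Coordinates are 1-based inclusive internally, matching how positions are
printed in the mouse genetics literature; BED output converts to 0-based
half-open. Heterozygous ("H") and no-call ("N") genotypes are loaded as
cell-level missing values rather than dropping the variant, so a variant
remains classifiable from its remaining strains.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGT")
#: input codes treated as cell-level missing
MISSING_CODES = frozenset({"H", "N", "", "NA", "-"})

XCE_ALLELES = ("a", "e", "b", "c", "d", "f", "unknown")
#: allelic series by increasing strength (f, seen only in M. spicilegus,
#: is ordered weakest by convention; it never enters series-order logic
#: with a stated position in the literature)
XCE_SERIES_ORDER = ("a", "e", "b", "c", "d")

TISSUES = ("brain", "kidney", "liver", "other")
ASSAYS = ("pyro", "rnaseq")

DEFAULT_REFERENCE_STRAIN = "C57BL/6J"


class TableFormatError(ValueError):
    """Raised when an input table violates its contract."""


@dataclass(frozen=True)
class Variant:
    variant_id: str
    chrom: str
    pos_bp: int
    source: str = "array"  # "array" (genotyping array) or "wgs"


@dataclass
class GenotypeTable:
    """Variants x strains matrix of filtered base calls.

    ``calls`` holds single-character base calls; missing cells are ``None``.
    Rows are sorted by (chrom, pos_bp) and positions are strictly increasing
    within a chromosome.
    """

    variants: list[Variant]
    strains: list[str]
    calls: np.ndarray  # dtype=object, shape (n_variants, n_strains)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=object)
        if self.calls.shape != (len(self.variants), len(self.strains)):
            raise TableFormatError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.variants)} variants x {len(self.strains)} strains"
            )
        self._check_sorted()

    def _check_sorted(self) -> None:
        seen: dict[str, int] = {}
        for v in self.variants:
            prev = seen.get(v.chrom)
            if prev is not None and v.pos_bp <= prev:
                raise TableFormatError(
                    f"positions not strictly increasing on {v.chrom} at "
                    f"{v.variant_id} ({v.pos_bp} after {prev})"
                )
            seen[v.chrom] = v.pos_bp

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def strain_index(self, strain: str) -> int:
        try:
            return self.strains.index(strain)
        except ValueError:
            raise KeyError(f"strain {strain!r} not in genotype table") from None

    def row(self, i: int) -> dict[str, str | None]:
        return dict(zip(self.strains, self.calls[i]))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "variant_id": [v.variant_id for v in self.variants],
                "chrom": [v.chrom for v in self.variants],
                "pos_bp": [v.pos_bp for v in self.variants],
                "source": [v.source for v in self.variants],
            }
        )
        for j, s in enumerate(self.strains):
            df[s] = [c if c is not None else "N" for c in self.calls[:, j]]
        return df


@dataclass(frozen=True)
class StrainPanel:
    """Map from strain name to Xce allele, anchored to a reference strain."""

    entries: Mapping[str, str]
    reference_strain: str = DEFAULT_REFERENCE_STRAIN

    def __post_init__(self) -> None:
        entries = {k.strip(): v for k, v in self.entries.items()}
        object.__setattr__(self, "entries", entries)
        for strain, allele in entries.items():
            if allele not in XCE_ALLELES:
                raise TableFormatError(
                    f"unknown Xce allele {allele!r} for strain {strain!r}"
                )
        if self.reference_strain not in entries:
            raise TableFormatError(
                f"reference strain {self.reference_strain!r} missing from panel"
            )

    @property
    def reference_allele(self) -> str:
        return self.entries[self.reference_strain]

    def strains(self) -> list[str]:
        return list(self.entries)

    def phenotype_groups(self, alt_allele: str | None = None) -> tuple[list[str], list[str]]:
        """Return (group0, group1) strain lists for SDP classification.

        group0 carries the reference strain's allele (coded 0); group1
        carries ``alt_allele`` (coded 1). If ``alt_allele`` is None it is the
        unique other named allele in the panel. Strains with allele
        ``unknown`` or any third allele are left unassigned.
        """
        ref = self.reference_allele
        if alt_allele is None:
            others = sorted(
                {a for a in self.entries.values() if a not in (ref, "unknown")}
            )
            if len(others) != 1:
                raise TableFormatError(
                    "alt_allele is ambiguous; panel carries alleles "
                    f"{others} besides reference allele {ref!r}"
                )
            alt_allele = others[0]
        group0 = [s for s, a in self.entries.items() if a == ref]
        group1 = [s for s, a in self.entries.items() if a == alt_allele]
        if not group0 or not group1:
            raise TableFormatError(
                "both phenotype groups must be nonempty "
                f"(group0={group0}, group1={group1})"
            )
        return group0, group1

    def with_strains(self, new_entries: Mapping[str, str]) -> "StrainPanel":
        merged = dict(self.entries)
        merged.update(new_entries)
        return StrainPanel(merged, self.reference_strain)


@dataclass(frozen=True)
class XCIMeasurement:
    """One allele-specific expression reading for one F1 female.

    Exactly one of ``maternal_fraction`` or the read-count pair is populated
    on input; count-mode rows are converted to fractions at load (Jeffreys
    add-0.5 by default) so downstream modeling sees a single scale.
    """

    mouse_id: str
    dam: str
    sire: str
    tissue: str
    gene: str
    assay: str
    maternal_fraction: float | None = None
    maternal_reads: int | None = None
    paternal_reads: int | None = None

    def __post_init__(self) -> None:
        if self.tissue not in TISSUES:
            raise TableFormatError(f"unknown tissue {self.tissue!r}")
        if self.assay not in ASSAYS:
            raise TableFormatError(f"unknown assay {self.assay!r}")
        has_frac = self.maternal_fraction is not None
        has_counts = self.maternal_reads is not None or self.paternal_reads is not None
        if has_frac == has_counts:
            raise TableFormatError(
                "exactly one of maternal_fraction / read-count pair required "
                f"(mouse {self.mouse_id}, gene {self.gene})"
            )
        if has_frac and not (0.0 <= self.maternal_fraction <= 1.0):
            raise TableFormatError(
                f"maternal_fraction {self.maternal_fraction} outside [0,1] "
                f"(mouse {self.mouse_id}, gene {self.gene})"
            )
        if has_counts:
            m, p = self.maternal_reads, self.paternal_reads
            if m is None or p is None or m < 0 or p < 0 or m + p == 0:
                raise TableFormatError(
                    "count-mode measurement needs nonnegative reads with a "
                    f"positive total (mouse {self.mouse_id}, gene {self.gene})"
                )

    @property
    def cross(self) -> tuple[str, str]:
        """Ordered (dam, sire) pair; reciprocal crosses are distinct."""
        return (self.dam, self.sire)

    def fraction(self, count_policy: str = "jeffreys") -> float:
        """Maternal fraction, converting read counts if necessary."""
        if self.maternal_fraction is not None:
            return self.maternal_fraction
        return count_to_fraction(self.maternal_reads, self.paternal_reads, count_policy)


def count_to_fraction(maternal: int, paternal: int, policy: str = "jeffreys") -> float:
    """Convert allele-specific read counts to a maternal fraction.

    ``jeffreys`` (default) uses the posterior mean under a Jeffreys
    Beta(1/2, 1/2) prior, (m + 0.5)/(m + p + 1); ``mle`` is the raw ratio.
    """
    if maternal < 0 or paternal < 0 or maternal + paternal == 0:
        raise ValueError("counts must be nonnegative with a positive total")
    if policy == "jeffreys":
        return (maternal + 0.5) / (maternal + paternal + 1.0)
    if policy == "mle":
        return maternal / (maternal + paternal)
    raise ValueError(f"unknown count policy {policy!r}")


@dataclass
class RunConfig:
    """Run-wide knobs: seeds, MCMC settings, thresholds."""

    seed: int = 0
    chains: int = 4
    iterations: int = 10_000
    burn_in: int = 2_000
    alpha_share: float = 0.05  # tail-probability threshold for allele sharing
    min_count: int = 5         # consistent variants required per candidate run
    epsilon: float = 0.005     # boundary clamp for fractions
    n_perm: int = 10_000
    count_policy: str = "jeffreys"

    def __post_init__(self) -> None:
        if min(self.chains, self.iterations, self.burn_in, self.min_count, self.n_perm) <= 0:
            raise ValueError("all counts must be positive")
        if self.burn_in >= self.iterations:
            raise ValueError("burn_in must be smaller than iterations")
        if not 0.0 < self.epsilon <= 0.05:
            raise ValueError("epsilon must lie in (0, 0.05]")
        if not 0.0 < self.alpha_share < 0.5:
            raise ValueError("alpha_share must lie in (0, 0.5)")


# ---------------------------------------------------------------------------
# readers


def _open_text(path_or_buf) -> io.TextIOBase:
    if hasattr(path_or_buf, "read"):
        return path_or_buf
    return open(path_or_buf, "r", newline="")


def read_genotype_table(path, panel: StrainPanel, sep: str | None = None) -> GenotypeTable:
    """Load a delimited genotype table restricted to the panel's strains.

    Required columns: variant_id, chrom, pos_bp; optional source; one column
    per strain. Calls are A/C/G/T; H (heterozygous) and N (no call) load as
    missing cells. Rows are sorted by (chrom, pos_bp); duplicate variant ids
    or duplicate positions on a chromosome are fatal.
    """
    df = pd.read_csv(path, sep=sep, engine="python", dtype=str, keep_default_na=False)
    required = {"variant_id", "chrom", "pos_bp"}
    missing = required - set(df.columns)
    if missing:
        raise TableFormatError(f"genotype table missing columns {sorted(missing)}")
    if panel.reference_strain not in df.columns:
        raise TableFormatError(
            f"genotype table lacks the reference strain column "
            f"{panel.reference_strain!r}"
        )
    strains = [s for s in panel.strains() if s in df.columns]
    absent = [s for s in panel.strains() if s not in df.columns]
    if absent:
        logger.info("panel strains absent from genotype table: %s", absent)

    dup = df["variant_id"][df["variant_id"].duplicated()]
    if len(dup):
        raise TableFormatError(f"duplicate variant ids: {sorted(set(dup))}")

    df["pos_bp"] = df["pos_bp"].astype(int)
    df = df.sort_values(["chrom", "pos_bp"], kind="mergesort").reset_index(drop=True)
    dup_pos = df.duplicated(subset=["chrom", "pos_bp"])
    if dup_pos.any():
        bad = df.loc[dup_pos, "variant_id"].tolist()
        raise TableFormatError(f"duplicate positions at variants {bad}")

    if "source" not in df.columns:
        df["source"] = "array"

    variants = [
        Variant(r.variant_id, r.chrom, int(r.pos_bp), r.source or "array")
        for r in df.itertuples()
    ]
    calls = np.empty((len(variants), len(strains)), dtype=object)
    n_missing = 0
    for j, s in enumerate(strains):
        col = df[s].str.strip().str.upper()
        for i, c in enumerate(col):
            if c in VALID_BASES:
                calls[i, j] = c
            elif c in MISSING_CODES:
                calls[i, j] = None
                n_missing += 1
            else:
                raise TableFormatError(
                    f"invalid call {c!r} for strain {s!r} at "
                    f"{variants[i].variant_id}"
                )
    logger.info(
        "loaded %d variants x %d strains (%d missing cells)",
        len(variants), len(strains), n_missing,
    )
    return GenotypeTable(variants, strains, calls)


def write_genotype_table(table: GenotypeTable, path, sep: str = ",") -> None:
    table.to_frame().to_csv(path, sep=sep, index=False)


def read_xci_table(path, count_policy: str = "jeffreys") -> list[XCIMeasurement]:
    """Load long-format allele-specific expression measurements.

    Columns: mouse_id, dam, sire, tissue, gene, assay, maternal_fraction,
    maternal_reads, paternal_reads. NA cells in the value columns drop that
    measurement (counted and logged); a fraction outside [0,1] is fatal with
    its row number.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"mouse_id", "dam", "sire", "tissue", "gene", "assay"}
    missing = required - set(df.columns)
    if missing:
        raise TableFormatError(f"XCI table missing columns {sorted(missing)}")

    out: list[XCIMeasurement] = []
    n_skipped = 0
    for idx, r in enumerate(df.itertuples(), start=2):  # header is line 1
        frac_raw = getattr(r, "maternal_fraction", "").strip()
        m_raw = getattr(r, "maternal_reads", "").strip()
        p_raw = getattr(r, "paternal_reads", "").strip()
        frac = None if frac_raw in ("", "NA") else float(frac_raw)
        m = None if m_raw in ("", "NA") else int(m_raw)
        p = None if p_raw in ("", "NA") else int(p_raw)
        if frac is None and m is None and p is None:
            n_skipped += 1
            continue
        if frac is not None and not (0.0 <= frac <= 1.0):
            raise TableFormatError(
                f"maternal_fraction {frac} outside [0,1] at row {idx}"
            )
        try:
            out.append(
                XCIMeasurement(
                    mouse_id=r.mouse_id.strip(),
                    dam=r.dam.strip(),
                    sire=r.sire.strip(),
                    tissue=r.tissue.strip(),
                    gene=r.gene.strip(),
                    assay=r.assay.strip(),
                    maternal_fraction=frac,
                    maternal_reads=m,
                    paternal_reads=p,
                )
            )
        except TableFormatError as e:
            raise TableFormatError(f"row {idx}: {e}") from None
    logger.info("loaded %d measurements, skipped %d NA rows", len(out), n_skipped)
    return out


def write_xci_table(measurements: Sequence[XCIMeasurement], path) -> None:
    rows = []
    for m in measurements:
        rows.append(
            {
                "mouse_id": m.mouse_id,
                "dam": m.dam,
                "sire": m.sire,
                "tissue": m.tissue,
                "gene": m.gene,
                "assay": m.assay,
                "maternal_fraction": "" if m.maternal_fraction is None else repr(m.maternal_fraction),
                "maternal_reads": "" if m.maternal_reads is None else m.maternal_reads,
                "paternal_reads": "" if m.paternal_reads is None else m.paternal_reads,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_strain_panel(path) -> StrainPanel:
    """Load a strain panel from YAML ({strains: {name: allele}, reference_strain})
    or two-column CSV (strain, xce_allele)."""
    p = Path(path)
    if p.suffix.lower() in (".yaml", ".yml"):
        with open(p) as fh:
            doc = yaml.safe_load(fh)
        return StrainPanel(
            doc["strains"], doc.get("reference_strain", DEFAULT_REFERENCE_STRAIN)
        )
    df = pd.read_csv(p, dtype=str)
    if not {"strain", "xce_allele"} <= set(df.columns):
        raise TableFormatError("panel CSV needs columns strain, xce_allele")
    ref = DEFAULT_REFERENCE_STRAIN
    if "reference" in df.columns:
        flagged = df.loc[df["reference"].str.lower().isin(["true", "1", "yes"]), "strain"]
        if len(flagged):
            ref = flagged.iloc[0]
    return StrainPanel(dict(zip(df["strain"], df["xce_allele"])), ref)


# ---------------------------------------------------------------------------
# writers


def write_interval_bed(intervals: Iterable[tuple], path) -> None:
    """Write (chrom, start_bp, end_bp, label) intervals as BED.

    Input coordinates are 1-based inclusive; output is 0-based half-open, so
    a single-base feature [s, s] becomes (s-1, s). Deterministic ordering by
    (chrom, start, end, label).
    """
    rows = []
    for chrom, start, end, label in intervals:
        if end < start:
            raise ValueError(f"interval end {end} < start {start} ({label})")
        rows.append((str(chrom), int(start) - 1, int(end), str(label)))
    rows.sort()
    with open(path, "w") as fh:
        fh.write("# BED: 0-based half-open intervals\n")
        for chrom, s0, e0, label in rows:
            fh.write(f"{chrom}\t{s0}\t{e0}\t{label}\n")


def write_classification_tsv(records, path) -> None:
    """Write SDP classification records (from sdp_mapping) as TSV."""
    rows = [
        {
            "variant_id": r.variant_id,
            "pos_bp": r.pos_bp,
            "source": r.source,
            "class": r.classification,
            "monomorphic_flag": r.monomorphic_flag,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
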