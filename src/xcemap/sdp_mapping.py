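"""Strain distribution pattern (SDP) encoding, classification and interval scan.

Every diallelic variant in the candidate region is coded relative to the
reference strain (C57BL/6J): the reference allele is 0, the alternative
allele is 1, heterozygous/no-call cells are missing. The SDP is then
compared with the Xce phenotype partition of the strain panel — carriers of
the reference strain's allele (group 0, Xce^b in the classical panel)
against carriers of the alternative phenotype allele (group 1, Xce^a):

* consistent           — every non-missing group-1 strain is 1 and every
                         non-missing group-0 strain is 0 (the SDP perfectly
                         mirrors the phenotype partition);
* inconsistent         — some group-1 strain is 0 AND some group-0 strain
                         is 1 (the SDP contradicts the partition);
* partially consistent — anything else (including monomorphic all-zero
                         SDPs, which are additionally flagged).

A candidate interval is a maximal position-ordered run that is enriched in
consistent SDPs and contains no inconsistent ones. The minimum interval is
bounded by the first and last consistent variant of the winning run; the
maximum interval is open-bounded by the nearest flanking inconsistent
variants.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .io_tables import GenotypeTable, StrainPanel

CONSISTENT = "consistent"
INCONSISTENT = "inconsistent"
PARTIAL = "partially_consistent"

MISSING = -1  # SDP code for a missing cell


@dataclass
class SDPRecord:
    """One variant's strain distribution pattern and its 3-way class."""

    variant_id: str
    pos_bp: int
    source: str
    chrom: str
    sdp: dict[str, int]  # strain -> 0 / 1 / MISSING
    classification: str | None = None
    monomorphic_flag: bool = False
    multi_allelic: bool = False


@dataclass
class Interval:
    chrom: str
    start_bp: int
    end_bp: int

    @property
    def span_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


@dataclass
class RunStats:
    start_bp: int          # first consistent position in the run
    end_bp: int            # last consistent position in the run
    consistent_count: int
    segment_start_bp: int  # first variant position of the inconsistent-free segment
    segment_end_bp: int


@dataclass
class IntervalReport:
    """Minimum/maximum candidate intervals plus per-run statistics."""

    chrom: str | None
    min_interval: Interval | None
    max_interval: Interval | None          # open bounds: flanking inconsistent positions (or chrom ends)
    max_bound_ids: tuple[str | None, str | None] = (None, None)
    consistent_count: int = 0
    runs: list[RunStats] = field(default_factory=list)
    status: str = "ok"                     # "ok" or "no-interval"


def encode_sdp(
    calls: Mapping[str, str | None], panel: StrainPanel
) -> tuple[dict[str, int] | None, bool, bool]:
    """Code one variant's calls as 0/1/missing relative to the reference.

    Returns (sdp, monomorphic, multi_allelic); sdp is None when the
    reference strain's own call is missing (the variant cannot be polarized
    and is skipped).
    """
    ref_call = calls.get(panel.reference_strain)
    if ref_call is None:
        return None, False, False
    alleles = {c for c in calls.values() if c is not None}
    multi = len(alleles) > 2
    sdp: dict[str, int] = {}
    for strain in panel.strains():
        c = calls.get(strain)
        if c is None:
            sdp[strain] = MISSING
        else:
            sdp[strain] = 0 if c == ref_call else 1
    mono = all(v in (0, MISSING) for v in sdp.values())
    return sdp, mono, multi


def classify_sdp(
    sdp: Mapping[str, int], group1: Sequence[str], group0: Sequence[str]
) -> str:
    """3-way classification of an SDP against the phenotype partition.

    group1 are alternative-allele carriers (expected 1, Xce^a in the
    classical panel); group0 carry the reference strain's allele (expected
    0). Missing entries are ignored; a group with no informative call blocks
    the "consistent" verdict (classification falls through to partial).
    """
    if not group1 or not group0:
        raise ValueError("both phenotype groups must be nonempty")
    g1 = [sdp[s] for s in group1 if sdp.get(s, MISSING) != MISSING]
    g0 = [sdp[s] for s in group0 if sdp.get(s, MISSING) != MISSING]
    some_g1_zero = any(v == 0 for v in g1)
    some_g0_one = any(v == 1 for v in g0)
    if some_g1_zero and some_g0_one:
        return INCONSISTENT
    if g1 and g0 and not some_g1_zero and not some_g0_one:
        return CONSISTENT
    return PARTIAL


def classify_table(
    table: GenotypeTable,
    panel: StrainPanel,
    alt_allele: str | None = None,
) -> tuple[list[SDPRecord], dict[str, int]]:
    """Encode and classify every variant of a genotype table.

    Variants whose reference call is missing are skipped; multi-allelic
    variants are excluded from classification (recorded with class None).
    Returns the records plus drop counters.
    """
    group0, group1 = panel.phenotype_groups(alt_allele)
    records: list[SDPRecord] = []
    counters = Counter(skipped_no_reference=0, multi_allelic=0, classified=0)
    for i, v in enumerate(table.variants):
        calls = table.row(i)
        sdp, mono, multi = encode_sdp(calls, panel)
        if sdp is None:
            counters["skipped_no_reference"] += 1
            continue
        rec = SDPRecord(
            variant_id=v.variant_id,
            pos_bp=v.pos_bp,
            source=v.source,
            chrom=v.chrom,
            sdp=sdp,
            monomorphic_flag=mono,
            multi_allelic=multi,
        )
        if multi:
            counters["multi_allelic"] += 1
        else:
            rec.classification = classify_sdp(sdp, group1, group0)
            counters["classified"] += 1
        records.append(rec)
    return records, dict(counters)


def scan_intervals(records: Sequence[SDPRecord], min_count: int = 5) -> IntervalReport:
    """Locate the winning consistent run and the min/max candidate intervals.

    Candidate runs are the maximal segments between inconsistent variants
    that contain at least ``min_count`` consistent variants (partially
    consistent variants may sit inside). The winning run has the most
    consistent variants; ties break by longer consistent span, then by
    leftmost position. The minimum interval is [first, last] consistent
    position of the winning run; the maximum interval is bounded
    (exclusively) by the nearest flanking inconsistent variants, falling
    back to the first/last classified variant when none flank.
    """
    classified = sorted(
        (r for r in records if r.classification is not None),
        key=lambda r: r.pos_bp,
    )
    if not classified:
        return IntervalReport(None, None, None, status="no-interval")
    chroms = {r.chrom for r in classified}
    if len(chroms) > 1:
        raise ValueError(f"scan expects a single chromosome, got {sorted(chroms)}")
    chrom = chroms.pop()

    # split into inconsistent-free segments
    segments: list[list[SDPRecord]] = [[]]
    boundaries: list[SDPRecord | None] = [None]  # inconsistent record left of segment k
    for r in classified:
        if r.classification == INCONSISTENT:
            boundaries.append(r)
            segments.append([])
        else:
            segments[-1].append(r)
    boundaries.append(None)  # right flank of last segment

    runs: list[tuple[RunStats, SDPRecord | None, SDPRecord | None]] = []
    for k, seg in enumerate(segments):
        cons = [r for r in seg if r.classification == CONSISTENT]
        if len(cons) < min_count:
            continue
        stats = RunStats(
            start_bp=cons[0].pos_bp,
            end_bp=cons[-1].pos_bp,
            consistent_count=len(cons),
            segment_start_bp=seg[0].pos_bp,
            segment_end_bp=seg[-1].pos_bp,
        )
        runs.append((stats, boundaries[k], boundaries[k + 1]))

    all_stats = [r[0] for r in runs]
    if not runs:
        return IntervalReport(chrom, None, None, status="no-interval", runs=all_stats)

    def rank(item):
        s = item[0]
        return (-s.consistent_count, -(s.end_bp - s.start_bp), s.start_bp)

    best, left, right = min(runs, key=rank)
    min_iv = Interval(chrom, best.start_bp, best.end_bp)
    max_iv = Interval(
        chrom,
        left.pos_bp if left is not None else classified[0].pos_bp,
        right.pos_bp if right is not None else classified[-1].pos_bp,
    )
    return IntervalReport(
        chrom=chrom,
        min_interval=min_iv,
        max_interval=max_iv,
        max_bound_ids=(
            left.variant_id if left is not None else None,
            right.variant_id if right is not None else None,
        ),
        consistent_count=best.consistent_count,
        runs=all_stats,
    )


def brute_force_scan(records: Sequence[SDPRecord], min_count: int = 5) -> IntervalReport:
    """O(n^2) reference search over all subsegments; oracle for scan_intervals."""
    classified = sorted(
        (r for r in records if r.classification is not None),
        key=lambda r: r.pos_bp,
    )
    if not classified:
        return IntervalReport(None, None, None, status="no-interval")
    chrom = classified[0].chrom
    best = None  # (count, span, start, end)
    n = len(classified)
    for i in range(n):
        count = 0
        bad = False
        for j in range(i, n):
            cls = classified[j].classification
            if cls == INCONSISTENT:
                bad = True
            elif cls == CONSISTENT:
                count += 1
            if bad:
                break
            if (
                count >= min_count
                and classified[i].classification == CONSISTENT
                and classified[j].classification == CONSISTENT
            ):
                span = classified[j].pos_bp - classified[i].pos_bp
                key = (-count, -span, classified[i].pos_bp)
                if best is None or key < best[0]:
                    best = (key, classified[i].pos_bp, classified[j].pos_bp, count)
    if best is None:
        return IntervalReport(chrom, None, None, status="no-interval")
    _, start, end, count = best
    left = max(
        (r for r in classified if r.classification == INCONSISTENT and r.pos_bp < start),
        key=lambda r: r.pos_bp,
        default=None,
    )
    right = min(
        (r for r in classified if r.classification == INCONSISTENT and r.pos_bp > end),
        key=lambda r: r.pos_bp,
        default=None,
    )
    return IntervalReport(
        chrom=chrom,
        min_interval=Interval(chrom, start, end),
        max_interval=Interval(
            chrom,
            left.pos_bp if left is not None else classified[0].pos_bp,
            right.pos_bp if right is not None else classified[-1].pos_bp,
        ),
        max_bound_ids=(
            left.variant_id if left is not None else None,
            right.variant_id if right is not None else None,
        ),
        consistent_count=count,
    )


@dataclass
class RefinementReport:
    before: IntervalReport
    after: IntervalReport
    proximal_shift_kb: float
    distal_shift_kb: float
    consistent_before: int
    consistent_after: int


def refine_with_strains(
    table: GenotypeTable,
    base_panel: StrainPanel,
    added: Mapping[str, str],
    alt_allele: str | None = None,
    min_count: int = 5,
) -> RefinementReport:
    """Reclassify every SDP over the enlarged panel and report boundary shifts.

    ``added`` maps new strain names to their newly assigned Xce allele; each
    must have a genotype column in the table. Adding strains can only demote
    classifications, so the consistent set after refinement is a subset of
    the consistent set before (boundaries move inward or stay).
    Shifts are (old - new) boundary displacement in kb: a positive proximal
    shift means the proximal boundary moved distally (interval shrank).
    """
    for s in added:
        if s not in table.strains:
            raise KeyError(f"added strain {s!r} has no genotype column")
    before_recs, _ = classify_table(table, base_panel, alt_allele)
    enlarged = base_panel.with_strains(added)
    after_recs, _ = classify_table(table, enlarged, alt_allele)
    before = scan_intervals(before_recs, min_count)
    after = scan_intervals(after_recs, min_count)

    def shifts(b: IntervalReport, a: IntervalReport) -> tuple[float, float]:
        if b.min_interval is None or a.min_interval is None:
            return float("nan"), float("nan")
        prox = (a.min_interval.start_bp - b.min_interval.start_bp) / 1_000.0
        dist = (b.min_interval.end_bp - a.min_interval.end_bp) / 1_000.0
        return prox, dist

    prox, dist = shifts(before, after)
    n_before = sum(1 for r in before_recs if r.classification == CONSISTENT)
    n_after = sum(1 for r in after_recs if r.classification == CONSISTENT)
    return RefinementReport(
        before=before,
        after=after,
        proximal_shift_kb=prox,
        distal_shift_kb=dist,
        consistent_before=n_before,
        consistent_after=n_after,
    )
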