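"""Targetable-repeat discovery from guide binding sites.

Binding sites are binned into fixed 10-kb genome bins; maximal runs of
adjacent occupied bins form binding clusters. A guide's target cluster
is its most site-rich cluster. Guides are screened with three
successive abundance/specificity filters (strict inequalities):

  (i)  > ``chromosome_threshold`` sites on some single chromosome,
  (ii) > ``cluster_threshold`` sites in some single cluster,
  (iii) no cluster on a non-target chromosome with
        > ``offtarget_cluster_threshold`` sites.

Target clusters of passing guides that overlap (share >= 1 bp; abutting
half-open intervals do not merge) are unioned into targetable repeats,
which are classified as centromeric when they overlap the centromere
annotation or a CENP-A peak by at least one base.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import pandas as pd

from .genome import ReferenceGenome
from .search import (
    BindingSite,
    GuideRNA,
    count_sites_per_chromosome,
    enumerate_protospacers,
    find_binding_sites,
)


@dataclass(frozen=True)
class BindingCluster:
    """A maximal run of adjacent occupied bins for one guide."""

    guide_id: str
    chrom: str
    start: int
    end: int
    site_count: int


@dataclass(frozen=True)
class FilterOutcome:
    guide_id: str
    pass_chromosome_abundance: bool
    pass_cluster_abundance: bool
    pass_specificity: bool
    target_cluster: BindingCluster | None = None
    failure_reason: str = ""

    @property
    def passed(self) -> bool:
        return (
            self.pass_chromosome_abundance
            and self.pass_cluster_abundance
            and self.pass_specificity
        )


@dataclass(frozen=True)
class TargetableRepeat:
    chrom: str
    start: int
    end: int
    contributing_guide_ids: frozenset[str]
    max_site_count: int
    repeat_class: str = "unclassified"  # centromeric | noncentromeric
    subclass: str = "unassigned"  # pericentromeric | telomere_proximal | unassigned


@dataclass
class AnnotationSet:
    """Centromere and CENP-A intervals plus chromosome lengths.

    Intervals are 0-based half-open, sorted per chromosome. Telomeres
    are taken as positions 0 and the chromosome length.
    """

    centromeres: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    cenpA_peaks: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    chromosome_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, table in (("centromeres", self.centromeres),
                            ("cenpA_peaks", self.cenpA_peaks)):
            for chrom, ivs in table.items():
                table[chrom] = sorted((int(s), int(e)) for s, e in ivs)
                for s, e in table[chrom]:
                    if not 0 <= s < e:
                        raise ValueError(f"{name}/{chrom}: bad interval [{s}, {e})")
                    length = self.chromosome_lengths.get(chrom)
                    if length is not None and e > length:
                        raise ValueError(
                            f"{name}/{chrom}: interval [{s}, {e}) exceeds length {length}"
                        )


def cluster_binding_sites(
    sites,
    bin_size: int = 10_000,
    chrom_lengths: dict[str, int] | None = None,
    chrom_order: list[str] | None = None,
) -> list[BindingCluster]:
    """Merge adjacent occupied bins (anchored at coordinate 0) into clusters.

    A site is assigned to the bin containing its start coordinate.
    Cluster ends are clipped to the chromosome length when known.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    sites = list(sites)
    if not sites:
        return []
    guide_ids = {s.guide_id for s in sites}
    if len(guide_ids) > 1:
        raise ValueError(f"sites must come from one guide, got {sorted(guide_ids)}")
    guide_id = sites[0].guide_id
    per_chrom: dict[str, dict[int, int]] = {}
    for s in sites:
        bins = per_chrom.setdefault(s.chrom, {})
        b = s.start // bin_size
        bins[b] = bins.get(b, 0) + 1
    key = (chrom_order.index if chrom_order else None)
    chroms = sorted(per_chrom, key=key) if key else sorted(per_chrom)
    clusters: list[BindingCluster] = []
    for chrom in chroms:
        bins = per_chrom[chrom]
        run_start = run_end = None
        run_count = 0
        for b in sorted(bins):
            if run_start is None:
                run_start, run_end, run_count = b, b, bins[b]
            elif b == run_end + 1:
                run_end, run_count = b, run_count + bins[b]
            else:
                clusters.append(_emit(guide_id, chrom, run_start, run_end,
                                      run_count, bin_size, chrom_lengths))
                run_start, run_end, run_count = b, b, bins[b]
        clusters.append(_emit(guide_id, chrom, run_start, run_end,
                              run_count, bin_size, chrom_lengths))
    return clusters


def _emit(guide_id, chrom, b0, b1, count, bin_size, chrom_lengths) -> BindingCluster:
    end = (b1 + 1) * bin_size
    if chrom_lengths and chrom in chrom_lengths:
        end = min(end, chrom_lengths[chrom])
    return BindingCluster(guide_id, chrom, b0 * bin_size, end, count)


def primary_target_cluster(
    clusters, chrom_order: list[str] | None = None
) -> BindingCluster:
    """The cluster with the most sites; ties go to earliest genomic position."""
    clusters = list(clusters)
    if not clusters:
        raise ValueError("primary_target_cluster requires at least one cluster")
    rank = (chrom_order.index if chrom_order else None)

    def sort_key(c: BindingCluster):
        pos = rank(c.chrom) if rank else c.chrom
        return (-c.site_count, pos, c.start)

    return min(clusters, key=sort_key)


def apply_guide_filters(
    guide_id: str,
    sites,
    chromosome_threshold: int = 500,
    cluster_threshold: int = 500,
    offtarget_cluster_threshold: int = 40,
    bin_size: int = 10_000,
    chrom_lengths: dict[str, int] | None = None,
    chrom_order: list[str] | None = None,
) -> FilterOutcome:
    """Apply the three successive abundance/specificity filters to one guide.

    Sites are expected at mismatch budget 0. Filters short-circuit and a
    human-readable failure_reason records the first failing step.
    """
    sites = list(sites)
    per_chrom = count_sites_per_chromosome(sites)
    if not any(n > chromosome_threshold for n in per_chrom.values()):
        best = max(per_chrom.values(), default=0)
        return FilterOutcome(
            guide_id, False, False, False,
            failure_reason=f"max per-chromosome site count {best} "
                           f"<= {chromosome_threshold}",
        )
    clusters = cluster_binding_sites(sites, bin_size, chrom_lengths, chrom_order)
    target = primary_target_cluster(clusters, chrom_order)
    if target.site_count <= cluster_threshold:
        return FilterOutcome(
            guide_id, True, False, False,
            failure_reason=f"max cluster site count {target.site_count} "
                           f"<= {cluster_threshold}",
        )
    offenders = [
        c for c in clusters
        if c.chrom != target.chrom and c.site_count > offtarget_cluster_threshold
    ]
    if offenders:
        worst = max(offenders, key=lambda c: c.site_count)
        return FilterOutcome(
            guide_id, True, True, False,
            failure_reason=f"off-target cluster on {worst.chrom} with "
                           f"{worst.site_count} sites > {offtarget_cluster_threshold}",
        )
    return FilterOutcome(guide_id, True, True, True, target_cluster=target)


def merge_targetable_repeats(target_clusters) -> list[TargetableRepeat]:
    """Union overlapping target clusters (same chromosome) into repeats.

    Overlap means shared base pairs under half-open intervals; abutting
    clusters (end == start) stay separate. Merging is transitive.
    """
    by_chrom: dict[str, list[BindingCluster]] = {}
    for c in target_clusters:
        by_chrom.setdefault(c.chrom, []).append(c)
    repeats: list[TargetableRepeat] = []
    for chrom in sorted(by_chrom):
        group = sorted(by_chrom[chrom], key=lambda c: (c.start, c.end))
        cur = [group[0]]
        cur_end = group[0].end
        for c in group[1:]:
            if c.start < cur_end:  # strict: abutment does not merge
                cur.append(c)
                cur_end = max(cur_end, c.end)
            else:
                repeats.append(_repeat_from(cur))
                cur, cur_end = [c], c.end
        repeats.append(_repeat_from(cur))
    return repeats


def _repeat_from(members: list[BindingCluster]) -> TargetableRepeat:
    return TargetableRepeat(
        chrom=members[0].chrom,
        start=min(c.start for c in members),
        end=max(c.end for c in members),
        contributing_guide_ids=frozenset(c.guide_id for c in members),
        max_site_count=max(c.site_count for c in members),
    )


def _overlaps_any(start: int, end: int, intervals) -> bool:
    return any(start < e and s < end for s, e in intervals)


def classify_repeat(
    repeat: TargetableRepeat,
    annotations: AnnotationSet,
    subclass_rule: str = "nearest",
) -> TargetableRepeat:
    """Set repeat_class (and subclass for noncentromeric repeats).

    Centromeric iff the repeat shares at least one base with a
    centromere annotation or a CENP-A peak. Noncentromeric repeats get
    an advisory subclass: with the default "nearest" rule the nearer of
    centromere vs telomere (by Mb distance) wins; rule "none" leaves the
    subclass unassigned.
    """
    if repeat.chrom not in annotations.chromosome_lengths:
        raise KeyError(f"chromosome {repeat.chrom!r} missing from annotations")
    cen = annotations.centromeres.get(repeat.chrom, [])
    peaks = annotations.cenpA_peaks.get(repeat.chrom, [])
    if _overlaps_any(repeat.start, repeat.end, cen) or _overlaps_any(
        repeat.start, repeat.end, peaks
    ):
        return replace(repeat, repeat_class="centromeric", subclass="unassigned")
    subclass = "unassigned"
    if subclass_rule == "nearest" and cen:
        d_cen, d_telo = annotate_distances(
            (repeat.chrom, repeat.start, repeat.end), annotations
        )
        subclass = "pericentromeric" if d_cen <= d_telo else "telomere_proximal"
    return replace(repeat, repeat_class="noncentromeric", subclass=subclass)


def annotate_distances(interval, annotations: AnnotationSet) -> tuple[float, float]:
    """(distance to centromere, distance to nearest telomere), in Mb, 1 dp.

    Distances are edge gaps in bp (0.0 when overlapping); telomeres are
    the chromosome ends. Centromere distance is NaN when the chromosome
    has no centromere annotation.
    """
    chrom, start, end = interval
    if chrom not in annotations.chromosome_lengths:
        raise KeyError(f"chromosome {chrom!r} missing from annotations")
    length = annotations.chromosome_lengths[chrom]
    cen = annotations.centromeres.get(chrom, [])
    if cen:
        gaps = []
        for s, e in cen:
            if start < e and s < end:
                gaps.append(0)
            elif end <= s:
                gaps.append(s - end)
            else:
                gaps.append(start - e)
        d_cen = round(min(gaps) / 1e6, 1)
    else:
        d_cen = math.nan
    d_telo = round(min(start, length - end) / 1e6, 1)
    return d_cen, d_telo


def discover_repeats(
    genome: ReferenceGenome,
    annotations: AnnotationSet,
    guide_lengths=(11, 15, 20),
    pam: str = "NGG",
    chromosome_threshold: int = 500,
    cluster_threshold: int = 500,
    offtarget_cluster_threshold: int = 40,
    bin_size: int = 10_000,
    mismatch_budgets=(0, 1, 2),
    subclass_rule: str = "nearest",
) -> tuple[pd.DataFrame, pd.DataFrame, list[TargetableRepeat]]:
    """End-to-end targetable-repeat discovery.

    Enumerates every PAM-adjacent protospacer at each configured guide
    length, collapses identical protospacer sequences to one query, uses
    the enumeration itself as the exact-match (0-mismatch) site list per
    unique sequence, applies the three filters, merges passing guides'
    target clusters into repeats and classifies/annotates them.

    Returns (guide_table, repeat_table, repeats). The guide table covers
    passing guides only, with target-cluster coordinates, Mb distances
    to centromere/telomere and cumulative site counts at the configured
    mismatch budgets. Deterministic given inputs and configuration.
    """
    chrom_order = genome.names
    lengths = genome.lengths
    outcomes: list[tuple[GuideRNA, FilterOutcome]] = []
    for L in sorted(set(int(x) for x in guide_lengths)):
        by_seq: dict[str, list[BindingSite]] = {}
        for g, site in enumerate_protospacers(genome, L, pam):
            by_seq.setdefault(g.protospacer, []).append(site)
        for seq, sites in by_seq.items():
            # filter (i) needs > chromosome_threshold on one chromosome;
            # the total count bounds that, so sparse guides exit early
            if len(sites) <= chromosome_threshold:
                continue
            gid = f"N{L}_{seq}"
            sites = [replace(s, guide_id=gid) for s in sites]
            outcome = apply_guide_filters(
                gid, sites,
                chromosome_threshold, cluster_threshold,
                offtarget_cluster_threshold, bin_size, lengths, chrom_order,
            )
            if outcome.passed:
                outcomes.append((GuideRNA(gid, seq, pam), outcome))

    budgets = sorted(set(int(b) for b in mismatch_budgets))
    guide_rows = []
    for guide, outcome in outcomes:
        tc = outcome.target_cluster
        d_cen, d_telo = annotate_distances((tc.chrom, tc.start, tc.end), annotations)
        row = {
            "guide_id": guide.id,
            "sequence": guide.protospacer,
            "length": guide.length,
            "pam": guide.pam,
            "target_chrom": tc.chrom,
            "target_start": tc.start,
            "target_end": tc.end,
            "target_site_count": tc.site_count,
            "dist_cen_mb": d_cen,
            "dist_telo_mb": d_telo,
        }
        if budgets:
            max_b = max(budgets)
            all_sites = find_binding_sites(guide, genome, max_b)
            for b in budgets:
                row[f"sites_mm{b}"] = sum(1 for s in all_sites if s.mismatches <= b)
        guide_rows.append(row)
    guide_table = pd.DataFrame(guide_rows)

    repeats = merge_targetable_repeats(
        [o.target_cluster for _, o in outcomes]
    )
    repeats = [classify_repeat(r, annotations, subclass_rule) for r in repeats]
    repeats.sort(key=lambda r: (chrom_order.index(r.chrom)
                                if r.chrom in chrom_order else len(chrom_order),
                                r.start))
    repeat_table = pd.DataFrame(
        [
            {
                "chrom": r.chrom,
                "start": r.start,
                "end": r.end,
                "class": r.repeat_class,
                "subclass": r.subclass,
                "n_guides": len(r.contributing_guide_ids),
                "max_site_count": r.max_site_count,
            }
            for r in repeats
        ]
    )
    return guide_table, repeat_table, repeats
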