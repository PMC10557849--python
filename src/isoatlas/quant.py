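"""Splicing quantification: PSI, terminal-exon usage, differential events.

PSI (percent spliced-in) is the inclusion rate of an event among all reads
covering it.  For junctions the denominator is the Leafcutter-style cluster
of junctions sharing a donor or acceptor; for cassette exons it combines
flanking inclusion junctions with exclusion introns that span the exon.
Undefined ratios (zero denominator) are encoded as NaN, never as 0 —
absence of evidence is not evidence of exclusion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .atlas import CuratedAtlas, JunctionCountMatrix, cpm
from .model import Exon, ExonRole, SpliceJunction

log = logging.getLogger(__name__)


@dataclass
class PsiTable:
    """Per-event, per-sample inclusion fractions with their denominators.

    ``psi`` is events x samples with NaN where the denominator is zero;
    ``denominator`` holds the read totals the fractions were computed over.
    """

    psi: pd.DataFrame
    denominator: pd.DataFrame
    event_kind: pd.Series  # event id -> {junction, exon, first_exon, last_exon}

    def __post_init__(self) -> None:
        vals = self.psi.to_numpy(dtype=float)
        defined = ~np.isnan(vals)
        if defined.any() and ((vals[defined] < -1e-9) | (vals[defined] > 1 + 1e-9)).any():
            raise ValueError("psi outside [0, 1]")


@dataclass
class DifferentialEvent:
    event: object
    group_a: str
    group_b: str
    delta_psi: float
    p_value: float
    q_value: float = float("nan")


def junction_clusters(junctions) -> list:
    """Partition junctions into connected components of the
    share-a-donor-or-acceptor graph.

    Two junctions are linked when they share a donor end or an acceptor
    start (same chrom/strand); components define the PSI denominator.
    """
    g = nx.Graph()
    keys = [j.key() for j in junctions]
    g.add_nodes_from(keys)
    by_end: dict = {}
    for chrom, d, a, strand in keys:
        by_end.setdefault((chrom, "donor", d, strand), []).append((chrom, d, a, strand))
        by_end.setdefault((chrom, "acceptor", a, strand), []).append(
            (chrom, d, a, strand)
        )
    for members in by_end.values():
        for other in members[1:]:
            g.add_edge(members[0], other)
    return [sorted(comp) for comp in nx.connected_components(g)]


def psi_junction(matrix: JunctionCountMatrix, clusters=None) -> PsiTable:
    """PSI of each junction within its shared-end cluster, per sample."""
    if clusters is None:
        clusters = junction_clusters(matrix.junctions)
    row_of = {key: i for i, key in enumerate(matrix.keys)}
    counts = matrix.counts.astype(float)
    psi = np.full_like(counts, np.nan)
    denom = np.zeros_like(counts)
    for cluster in clusters:
        rows = [row_of[k] for k in cluster if k in row_of]
        if len(rows) != len(cluster):
            missing = set(cluster) - set(matrix.keys)
            raise ValueError(f"cluster references junctions not in matrix: {missing}")
        total = counts[rows].sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(total > 0, counts[rows] / total, np.nan)
        psi[rows] = frac
        denom[rows] = total
    index = pd.Index(matrix.keys, name="junction", tupleize_cols=False)
    return PsiTable(
        psi=pd.DataFrame(psi, index=index, columns=matrix.samples),
        denominator=pd.DataFrame(denom.astype(int), index=index, columns=matrix.samples),
        event_kind=pd.Series("junction", index=index),
    )


def _exon_flanking_junctions(exon: Exon, atlas: CuratedAtlas):
    """Inclusion (acceptor at exon start / donor at exon end) and exclusion
    (intron strictly containing the exon) junction keys from the atlas."""
    upstream, downstream, exclusion = [], [], []
    for j in atlas.junctions:
        if j.chrom != exon.chrom or j.strand != exon.strand:
            continue
        if j.acceptor_start == exon.start:
            upstream.append(j.key())
        if j.donor_end == exon.end:
            downstream.append(j.key())
        if j.donor_end < exon.start and j.acceptor_start > exon.end:
            exclusion.append(j.key())
    return upstream, downstream, exclusion


def psi_exon(matrix: JunctionCountMatrix, exon: Exon, atlas: CuratedAtlas) -> PsiTable:
    """Cassette-exon PSI: mean flanking inclusion over inclusion + exclusion.

    psi = mean(up, down) / (mean(up, down) + exclusion_total); NaN where no
    informative reads cover the event.
    """
    upstream, downstream, exclusion = _exon_flanking_junctions(exon, atlas)
    row_of = {key: i for i, key in enumerate(matrix.keys)}

    def total(keys):
        rows = [row_of[k] for k in keys if k in row_of]
        if not rows:
            return np.zeros(len(matrix.samples))
        return matrix.counts[rows].sum(axis=0).astype(float)

    if not upstream and not downstream:
        psi = np.full(len(matrix.samples), np.nan)
        denom = np.zeros(len(matrix.samples))
    else:
        up = total(upstream)
        down = total(downstream)
        if upstream and downstream:
            inclusion = (up + down) / 2.0
        else:  # one flank only: use what exists
            inclusion = up + down
        excl = total(exclusion)
        denom = inclusion + excl
        with np.errstate(invalid="ignore", divide="ignore"):
            psi = np.where(denom > 0, inclusion / denom, np.nan)

    event = (exon.chrom, exon.start, exon.end, exon.strand)
    index = pd.Index([event], tupleize_cols=False)
    return PsiTable(
        psi=pd.DataFrame([psi], index=index, columns=matrix.samples),
        denominator=pd.DataFrame(
            [np.round(denom).astype(int)], index=index, columns=matrix.samples
        ),
        event_kind=pd.Series("exon", index=index),
    )


def terminal_exon_usage(
    matrix: JunctionCountMatrix, atlas: CuratedAtlas, side: str
) -> PsiTable:
    """Usage of each first (or last) exon as a fraction of all of them.

    Expression of a terminal exon is proxied by the junction reads leaving
    it (first exons) or entering it (last exons), which keeps the measure
    junction-based like the rest of the pipeline.
    """
    if side not in ("first", "last"):
        raise ValueError("side must be 'first' or 'last'")
    exons = atlas.first_exons if side == "first" else atlas.last_exons
    if not exons:
        raise ValueError(f"atlas marks no {side} exons")

    counts = matrix.counts.astype(float)
    expr = np.zeros((len(exons), len(matrix.samples)))
    for i, exon in enumerate(exons):
        for r, j in enumerate(matrix.junctions):
            if j.chrom != exon.chrom or j.strand != exon.strand:
                continue
            if side == "first":
                # junction leaving the terminal exon, in transcript orientation
                hit = (
                    j.donor_end == exon.end
                    if exon.strand == "+"
                    else j.acceptor_start == exon.start
                )
            else:
                hit = (
                    j.acceptor_start == exon.start
                    if exon.strand == "+"
                    else j.donor_end == exon.end
                )
            if hit:
                expr[i] += counts[r]

    total = expr.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        usage = np.where(total > 0, expr / total, np.nan)
    events = [(e.chrom, e.start, e.end, e.strand) for e in exons]
    index = pd.Index(events, tupleize_cols=False)
    kind = "first_exon" if side == "first" else "last_exon"
    return PsiTable(
        psi=pd.DataFrame(usage, index=index, columns=matrix.samples),
        denominator=pd.DataFrame(
            np.tile(np.round(total).astype(int), (len(exons), 1)),
            index=index,
            columns=matrix.samples,
        ),
        event_kind=pd.Series(kind, index=index),
    )


def differential_events(
    psi: PsiTable, groups: dict, group_a: str | None = None, group_b: str | None = None
) -> list:
    """Wilcoxon rank-sum per event between two sample groups, BH-corrected.

    ``groups`` maps sample id -> group label.  Events with fewer than two
    defined PSI values in either group are skipped (logged).  delta_psi is
    mean(group_a) - mean(group_b).
    """
    labels = sorted(set(groups.values()))
    if group_a is None or group_b is None:
        if len(labels) != 2:
            raise ValueError("specify group_a/group_b when more than two groups")
        group_a, group_b = labels

    cols_a = [s for s in psi.psi.columns if groups.get(s) == group_a]
    cols_b = [s for s in psi.psi.columns if groups.get(s) == group_b]
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("need at least two samples per group")

    results = []
    for event, row in psi.psi.iterrows():
        a = row[cols_a].to_numpy(dtype=float)
        b = row[cols_b].to_numpy(dtype=float)
        a = a[~np.isnan(a)]
        b = b[~np.isnan(b)]
        if len(a) < 2 or len(b) < 2:
            log.debug("event %s skipped: <2 defined values in a group", event)
            continue
        if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
            p = 1.0
        else:
            p = stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
        results.append(
            DifferentialEvent(
                event=event,
                group_a=group_a,
                group_b=group_b,
                delta_psi=float(a.mean() - b.mean()),
                p_value=float(p),
            )
        )
    if results:
        qs = multipletests([r.p_value for r in results], method="fdr_bh")[1]
        for r, q in zip(results, qs):
            r.q_value = float(q)
    return results


def differential_frame(events) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "event": str(e.event),
                "group_a": e.group_a,
                "group_b": e.group_b,
                "delta_psi": e.delta_psi,
                "p_value": e.p_value,
                "q_value": e.q_value,
            }
            for e in events
        ]
    )
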