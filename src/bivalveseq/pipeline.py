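"""The amplicon analysis workflow: merge, trim, dereplicate, classify, report.

Stages, in the order they run on each sample:

1. **merge** - overlap-merge each read pair (R1 against the reverse
   complement of R2) at the maximal-scoring ungapped offset; base conflicts
   in the overlap resolve toward the higher-quality base, ties toward R1.
2. **trim** - require a forward-primer match at the 5' end and a
   reverse-primer match at the 3' end from the *same* family primer set
   (checking the flipped orientation before rejecting) and cut both primers
   off, leaving the barcode insert.
3. **dereplicate** - collapse exactly identical inserts into representative
   sequences with counts; no OTU clustering is performed.
4. **classify** - rank every database insert by global edit-distance
   identity; the best hit labels the cluster, ties collapse to the smallest
   resolution group or shared genus, and clusters below the identity
   threshold stay "unassigned".

Counts are conserved at every stage and reported per label as a percentage
of the reads passing the workflow (the merge+trim survivors), with a
detection convention of >= 1% for calling a component present.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import edlib
import numpy as np

from .primers import TriplexAssay, mismatch_count, revcomp
from .refdb import BarcodeDB

logger = logging.getLogger("bivalveseq")

UNASSIGNED = "unassigned"
AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class PipelineParams:
    """Tunable analysis parameters with their packaged defaults."""

    min_overlap: int = 20
    max_mismatch_frac: float = 0.1
    max_mm: int = 2  # per-primer mismatch tolerance during trimming
    min_identity: float = 0.97
    report_threshold_percent: float = 1.0


# ---------------------------------------------------------------------------
# Merge
# ---------------------------------------------------------------------------

def merge_pairs(
    r1: str,
    r2: str,
    q1: Optional[str] = None,
    q2: Optional[str] = None,
    min_overlap: int = 20,
    max_mismatch_frac: float = 0.1,
) -> Tuple[Optional[str], Optional[str]]:
    """Overlap-merge a read pair; returns ``(merged, None)`` or ``(None, reason)``.

    R2 is reverse-complemented and slid against R1 at every ungapped offset
    with overlap >= ``min_overlap``; the offset maximizing
    (matches - mismatches) wins, provided its mismatch fraction is at most
    ``max_mismatch_frac``. Overlap disagreements take the base with the
    higher quality character, ties going to R1.
    """
    if not r1 or not r2:
        return None, "empty-read"
    a = r1.upper()
    b = revcomp(r2.upper())
    qa = q1 or "I" * len(a)
    qb = (q2 or "I" * len(r2))[::-1]
    la, lb = len(a), len(b)
    aa = np.frombuffer(a.encode(), dtype=np.uint8)
    bb = np.frombuffer(b.encode(), dtype=np.uint8)

    best: Optional[Tuple[int, int, int]] = None  # (score, -mm, shift)
    # fast path: the full-overlap shift; if perfect it cannot be beaten
    full_shift = 0 if la >= lb else -(lb - la)
    for shift in [full_shift] + [
        s for s in range(-(lb - min_overlap), la - min_overlap + 1) if s != full_shift
    ]:
        a_lo, b_lo = max(shift, 0), max(-shift, 0)
        ovl = min(la - a_lo, lb - b_lo)
        if ovl < min_overlap:
            continue
        mm = int((aa[a_lo : a_lo + ovl] != bb[b_lo : b_lo + ovl]).sum())
        if mm > max_mismatch_frac * ovl:
            continue
        score = ovl - 2 * mm
        cand = (score, -mm, shift)
        if best is None or cand > best:
            best = cand
            if mm == 0 and ovl == min(la, lb):
                break  # perfect full overlap is optimal
    if best is None:
        return None, "no-overlap"

    _, neg_mm, shift = best
    a_lo, b_lo = max(shift, 0), max(-shift, 0)
    ovl = min(la - a_lo, lb - b_lo)
    head = a[:a_lo] if shift >= 0 else b[:b_lo]
    mid = []
    if -neg_mm == 0:
        mid_s = a[a_lo : a_lo + ovl]
    else:
        for i in range(ovl):
            ca, cb = a[a_lo + i], b[b_lo + i]
            if ca == cb or qa[a_lo + i] >= qb[b_lo + i]:
                mid.append(ca)
            else:
                mid.append(cb)
        mid_s = "".join(mid)
    tail = b[b_lo + ovl :] if la - a_lo <= lb - b_lo else a[a_lo + ovl :]
    return head + mid_s + tail, None


# ---------------------------------------------------------------------------
# Trim
# ---------------------------------------------------------------------------

def trim_primers(
    seq: str,
    assay: TriplexAssay,
    max_mm: int = 2,
) -> Tuple[Optional[str], Optional[str]]:
    """Strip the family primer pair off a merged read.

    Requires a forward primer at the 5' end and a reverse primer (as its
    reverse complement) at the 3' end from the same family set, each within
    ``max_mm`` mismatches; the flipped orientation is tried before
    rejecting. Returns ``(insert, family)`` on success, else
    ``(None, reason)`` with reason one of no-forward / no-reverse /
    family-conflict.
    """
    seq = seq.upper()
    fwd_families: set[str] = set()
    rev_families: set[str] = set()
    best: Optional[Tuple[int, str, str]] = None  # (total_mm, insert, family)
    for oriented in (seq, revcomp(seq)):
        n = len(oriented)
        for pset in assay.sets:
            for f in pset.forwards:
                lf = len(f.sequence)
                if n < lf:
                    continue
                mm_f = mismatch_count(f.sequence, oriented[:lf])
                if mm_f > max_mm:
                    continue
                fwd_families.add(pset.family)
                for r in pset.reverses:
                    lr = len(r.sequence)
                    if n < lf + lr:
                        continue
                    mm_r = mismatch_count(revcomp(r.sequence), oriented[n - lr :])
                    if mm_r > max_mm:
                        continue
                    cand = (mm_f + mm_r, oriented[lf : n - lr], pset.family)
                    if best is None or cand < best:
                        best = cand
            for r in pset.reverses:
                lr = len(r.sequence)
                if n >= lr and mismatch_count(
                    revcomp(r.sequence), oriented[n - lr :]
                ) <= max_mm:
                    rev_families.add(pset.family)
    if best is not None:
        return best[1], best[2]
    if not fwd_families:
        return None, "no-forward"
    if not rev_families:
        return None, "no-reverse"
    return None, "family-conflict"


# ---------------------------------------------------------------------------
# Dereplicate
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DerepCluster:
    representative: str
    count: int


def dereplicate(inserts: List[str]) -> List[DerepCluster]:
    """Collapse exactly identical sequences, sorted by count desc then sequence."""
    counts = Counter(s.upper() for s in inserts)
    return [
        DerepCluster(seq, n)
        for seq, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]


# ---------------------------------------------------------------------------
# Classify
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Assignment:
    representative: str
    label: str
    identity: float
    count: int


def _identity(query: str, target: str) -> float:
    d = edlib.align(query, target, task="distance")["editDistance"]
    return 1.0 - d / max(len(query), len(target))


def classify(
    cluster: DerepCluster,
    db: BarcodeDB,
    min_identity: float = 0.97,
) -> Assignment:
    """Assign a dereplicated representative against every database insert.

    Identity is 1 - editdist/max(len); the best-identity insert(s) win.
    When several species tie, the label collapses to their resolution group
    if they share one, else to "<Genus> spp." if they share a genus, else
    "ambiguous". Below ``min_identity`` the cluster is "unassigned".
    """
    if not db.inserts:
        raise ValueError("database has no inserts; run build_inserts first")
    best_ident = -1.0
    best_accs: list[str] = []
    for acc in sorted(db.inserts):
        ident = _identity(cluster.representative, db.inserts[acc])
        if ident > best_ident + 1e-12:
            best_ident, best_accs = ident, [acc]
        elif abs(ident - best_ident) <= 1e-12:
            best_accs.append(acc)
    if best_ident < min_identity:
        return Assignment(cluster.representative, UNASSIGNED, best_ident, cluster.count)
    species = {db.species_of(a) for a in best_accs}
    if len(species) == 1:
        sp = next(iter(species))
        group = db.group_of(sp)
        # a species sharing its insert with others can only be reported at
        # its group's rank
        label = group.label if group is not None else sp
    else:
        groups = {db.group_of(sp) for sp in species}
        if len(groups) == 1 and None not in groups:
            label = next(iter(groups)).label
        else:
            genera = {sp.split()[0] for sp in species}
            label = f"{next(iter(genera))} spp." if len(genera) == 1 else AMBIGUOUS
    return Assignment(cluster.representative, label, best_ident, cluster.count)


# ---------------------------------------------------------------------------
# Sample report
# ---------------------------------------------------------------------------

def percent_assigned(reads_assigned: int, reads_passing: int) -> float:
    """The report's percentage column: 100*assigned/passing at 2 decimals."""
    if reads_passing == 0:
        return 0.0
    return round(100.0 * reads_assigned / reads_passing, 2)


@dataclass
class SampleReport:
    sample_id: str
    total_raw_reads: int
    reads_passing_workflow: int
    label_counts: Dict[str, int] = field(default_factory=dict)
    rejection_counts: Dict[str, int] = field(default_factory=dict)
    assignments: List[Assignment] = field(default_factory=list)
    report_threshold_percent: float = 1.0

    @property
    def percent_assigned(self) -> Dict[str, float]:
        return {
            label: percent_assigned(n, self.reads_passing_workflow)
            for label, n in self.label_counts.items()
        }

    @property
    def detected_labels(self) -> List[str]:
        pct = self.percent_assigned
        return sorted(
            (
                l
                for l in self.label_counts
                if l != UNASSIGNED and pct[l] >= self.report_threshold_percent
            ),
            key=lambda l: -self.label_counts[l],
        )

    def to_rows(self) -> List[Dict[str, object]]:
        """Table rows in the study's report column layout."""
        rows = []
        pct = self.percent_assigned
        for label, n in sorted(self.label_counts.items(), key=lambda kv: -kv[1]):
            rows.append(
                {
                    "Sample ID": self.sample_id,
                    "Species Identified": label,
                    "Total Number of Raw Reads": self.total_raw_reads,
                    "Total Number of Reads Passing the Workflow": self.reads_passing_workflow,
                    "Number of Reads Assigned Correctly": n,
                    "Percentage of Reads Assigned Correctly (%)": pct[label],
                    "Detected": pct[label] >= self.report_threshold_percent
                    and label != UNASSIGNED,
                }
            )
        return rows


def _read_fastq(path: str | Path) -> List[Tuple[str, str, str]]:
    """(id, seq, qual) triples from an uncompressed Phred+33 FASTQ."""
    out = []
    path = Path(path)
    try:
        with open(path) as fh:
            while True:
                h = fh.readline()
                if not h:
                    break
                s = fh.readline().rstrip("\n")
                plus = fh.readline()
                q = fh.readline().rstrip("\n")
                if not h.startswith("@") or not plus.startswith("+") or len(s) != len(q):
                    raise ValueError(
                        f"malformed FASTQ record near {h.strip()!r} in {path}"
                    )
                out.append((h[1:].split()[0], s, q))
    except OSError as e:
        raise ValueError(f"unreadable FASTQ {path}: {e}") from e
    return out


def run_sample(
    fastq_r1: str | Path,
    fastq_r2: str | Path,
    db: BarcodeDB,
    assay: TriplexAssay,
    params: PipelineParams = PipelineParams(),
    sample_id: Optional[str] = None,
) -> SampleReport:
    """Run merge -> trim -> dereplicate -> classify on one paired sample.

    Identical read pairs are collapsed before merging (and identical merged
    sequences before trimming) purely as a computation shortcut; stage
    counts are aggregated so the result is identical to processing every
    pair individually.
    """
    sample_id = sample_id or Path(fastq_r1).stem
    reads1 = _read_fastq(fastq_r1)
    reads2 = _read_fastq(fastq_r2)
    if len(reads1) != len(reads2):
        raise ValueError(
            f"R1/R2 length mismatch: {len(reads1)} vs {len(reads2)} pairs"
        )
    total = len(reads1)
    rejections: Counter[str] = Counter()

    pair_counts: Counter[Tuple[str, str, str, str]] = Counter()
    for (_, s1, q1), (_, s2, q2) in zip(reads1, reads2):
        pair_counts[(s1, q1, s2, q2)] += 1

    merged_counts: Counter[str] = Counter()
    for (s1, q1, s2, q2), n in pair_counts.items():
        merged, reason = merge_pairs(
            s1, s2, q1, q2, params.min_overlap, params.max_mismatch_frac
        )
        if merged is None:
            rejections[f"merge:{reason}"] += n
        else:
            merged_counts[merged] += n

    insert_counts: Counter[str] = Counter()
    for merged, n in merged_counts.items():
        insert, family_or_reason = trim_primers(merged, assay, params.max_mm)
        if insert is None:
            rejections[f"trim:{family_or_reason}"] += n
        else:
            insert_counts[insert] += n

    passing = sum(insert_counts.values())
    clusters = [
        DerepCluster(seq, n)
        for seq, n in sorted(insert_counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    assignments = [classify(c, db, params.min_identity) for c in clusters]

    label_counts: Dict[str, int] = {}
    for a in assignments:
        label_counts[a.label] = label_counts.get(a.label, 0) + a.count

    report = SampleReport(
        sample_id=sample_id,
        total_raw_reads=total,
        reads_passing_workflow=passing,
        label_counts=label_counts,
        rejection_counts=dict(rejections),
        assignments=assignments,
        report_threshold_percent=params.report_threshold_percent,
    )
    logger.info(
        "sample %s: %d raw pairs, %d passing, %d clusters",
        sample_id,
        total,
        passing,
        len(clusters),
    )
    for reason, n in sorted(rejections.items()):
        logger.info("sample %s: rejected %d reads (%s)", sample_id, n, reason)
    return report
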