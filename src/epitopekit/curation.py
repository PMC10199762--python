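"""Benchmark-style dataset curation for linear B-cell epitope peptides.

The pipeline mirrors how experimental epitope collections are turned into
machine-learning benchmarks: keep peptides confirmed by at least two
distinct assays, restrict to lengths 6-25 (which covers ~99% of linear
epitopes), drop sequences reported as both epitope and non-epitope,
require a source organism, remove sequence redundancy at an identity
threshold, and finally draw a stratified train/test split that preserves
the class ratio.

Redundancy removal uses an internal greedy, length-descending,
representative-based clustering with a documented identity definition
(matches / alignment length under global alignment; Hamming matches /
length for equal-length strings), so results are deterministic and
testable without an external clustering binary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .io_formats import PeptideRecord

try:  # optional fast global aligner for unequal lengths
    from Bio import Align as _bio_align
except ImportError:  # pragma: no cover
    _bio_align = None


@dataclass
class CurationConfig:
    """Parameters of the five-step curation pipeline plus the split."""

    min_evidence: int = 2
    min_length: int = 6
    max_length: int = 25
    similarity_threshold: float = 0.95
    require_organism: bool = True
    test_fraction: float = 0.20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_length > self.max_length:
            raise ValueError("min_length must be <= max_length")
        if not (0 < self.similarity_threshold <= 1):
            raise ValueError("similarity_threshold must be in (0, 1]")
        if not (0 < self.test_fraction < 1):
            raise ValueError("test_fraction must be in (0, 1)")


@dataclass
class CurationReport:
    """Audit trail: survivor counts after each step, in pipeline order."""

    counts_per_step: list = field(default_factory=list)
    step_names: list = field(default_factory=list)
    removed_dual_class: int = 0
    clusters_formed: int = 0
    engine: str = "internal-greedy"

    def record(self, name: str, count: int) -> None:
        self.step_names.append(name)
        self.counts_per_step.append(count)

    def to_dict(self) -> dict:
        return {
            "steps": dict(zip(self.step_names, self.counts_per_step)),
            "counts_per_step": self.counts_per_step,
            "removed_dual_class": self.removed_dual_class,
            "clusters_formed": self.clusters_formed,
            "engine": self.engine,
        }


# ---------------------------------------------------------------------------
# Individual filters
# ---------------------------------------------------------------------------

def filter_evidence(records: Sequence[PeptideRecord], min_evidence: int) -> list:
    """Keep records confirmed by at least ``min_evidence`` distinct assays."""
    return [r for r in records if r.evidence_count >= min_evidence]


def filter_length(records: Sequence[PeptideRecord], min_length: int,
                  max_length: int) -> list:
    """Keep records with min_length <= len(sequence) <= max_length (inclusive)."""
    return [r for r in records if min_length <= len(r.sequence) <= max_length]


def remove_dual_class(records: Sequence[PeptideRecord]) -> list:
    """Drop every sequence reported as both epitope and non-epitope.

    All records of a conflicting sequence are removed; duplicate records
    within one class are untouched (deduplication is redundancy removal's
    job).
    """
    by_seq: dict = {}
    for r in records:
        if r.label in ("epitope", "non_epitope"):
            by_seq.setdefault(r.sequence, set()).add(r.label)
    conflicted = {s for s, labels in by_seq.items() if len(labels) > 1}
    return [r for r in records if r.sequence not in conflicted]


def dual_class_sequences(records: Sequence[PeptideRecord]) -> set:
    """The set of sequences present in both classes simultaneously."""
    by_seq: dict = {}
    for r in records:
        if r.label in ("epitope", "non_epitope"):
            by_seq.setdefault(r.sequence, set()).add(r.label)
    return {s for s, labels in by_seq.items() if len(labels) > 1}


def filter_organism(records: Sequence[PeptideRecord]) -> list:
    """Keep only records carrying a known source-organism class."""
    return [r for r in records if r.organism_class != "unknown"]


# ---------------------------------------------------------------------------
# Redundancy removal
# ---------------------------------------------------------------------------

def pairwise_identity(a: str, b: str) -> float:
    """Global-alignment sequence identity in [0, 1].

    Defined as matches / alignment length under a global alignment in which
    end gaps are penalized.  For equal-length strings this reduces exactly
    to Hamming matches / length; for unequal lengths a match-maximizing
    global alignment is used and the alignment length is its number of
    columns.
    """
    if len(a) == len(b):
        matches = sum(x == y for x, y in zip(a, b))
        return matches / len(a)
    if _bio_align is None:  # pragma: no cover - biopython is a hard dep
        raise RuntimeError("biopython required for unequal-length identity")
    aligner = _bio_align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    # tiny gap penalty: prefers compact alignments, keeps score ~= matches
    aligner.open_gap_score = -0.001
    aligner.extend_gap_score = -0.001
    aln = aligner.align(a, b)[0]
    matches = sum(
        x == y for x, y in zip(str(aln[0]), str(aln[1])) if x != "-" and y != "-"
    )
    return matches / aln.length


def _greedy_clusters(sequences: Sequence[str], threshold: float) -> list:
    """Greedy length-descending clustering; returns list of representative
    indices into ``sequences`` (first-seen longest per cluster)."""
    order = sorted(
        range(len(sequences)),
        key=lambda i: (-len(sequences[i]), sequences[i], i),
    )
    reps: list = []
    for i in order:
        seq = sequences[i]
        placed = False
        for rep_i in reps:
            if pairwise_identity(seq, sequences[rep_i]) >= threshold:
                placed = True
                break
        if not placed:
            reps.append(i)
    return reps


def remove_redundancy(records: Sequence[PeptideRecord],
                      similarity_threshold: float):
    """Cluster near-identical sequences and keep one representative each.

    Clustering runs within each class label independently, so it can never
    silently delete a cross-class conflict (those are handled earlier by
    :func:`remove_dual_class`).  Deterministic: sequences are processed in
    (length descending, lexicographic, input order); the representative is
    the first-seen longest member of its cluster.

    Returns ``(retained records in original input order, CurationReport)``
    where the report carries the number of clusters formed.
    """
    if not (0 < similarity_threshold <= 1):
        raise ValueError("similarity_threshold must be in (0, 1]")
    report = CurationReport()
    keep_idx: set = set()
    by_label: dict = {}
    for idx, r in enumerate(records):
        by_label.setdefault(r.label, []).append(idx)
    n_clusters = 0
    for label_indices in by_label.values():
        seqs = [records[i].sequence for i in label_indices]
        reps = _greedy_clusters(seqs, similarity_threshold)
        n_clusters += len(reps)
        keep_idx.update(label_indices[i] for i in reps)
    report.clusters_formed = n_clusters
    retained = [r for i, r in enumerate(records) if i in keep_idx]
    return retained, report


# ---------------------------------------------------------------------------
# Split
# ---------------------------------------------------------------------------

def stratified_split(records: Sequence[PeptideRecord], test_fraction: float,
                     seed: int):
    """Random class-stratified partition into (train, test).

    Per-class test counts are ``round(n_class * test_fraction)``, so class
    proportions are preserved within one record per class.  Reproducible
    under ``seed``; output preserves input order within each part.
    """
    if not (0 < test_fraction < 1):
        raise ValueError("test_fraction must be in (0, 1)")
    by_label: dict = {}
    for idx, r in enumerate(records):
        by_label.setdefault(r.label, []).append(idx)
    for label, idxs in by_label.items():
        if len(idxs) < 2:
            raise ValueError(
                f"cannot stratify: class {label!r} has only {len(idxs)} record(s)"
            )
    rng = np.random.default_rng(seed)
    test_idx: set = set()
    for label in sorted(by_label):
        idxs = np.array(by_label[label])
        n_test = int(round(len(idxs) * test_fraction))
        n_test = min(max(n_test, 1), len(idxs) - 1)  # both sides non-empty
        chosen = rng.choice(idxs, size=n_test, replace=False)
        test_idx.update(int(i) for i in chosen)
    train = [r for i, r in enumerate(records) if i not in test_idx]
    test = [r for i, r in enumerate(records) if i in test_idx]
    return train, test


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

def curate(records: Sequence[PeptideRecord], config: CurationConfig):
    """Run the full curation pipeline and stratified split.

    Order: evidence filter -> length filter -> dual-class removal ->
    organism requirement -> redundancy removal -> stratified split.
    Returns ``(train, test, CurationReport)``; the report records the
    survivor count after each step (monotone non-increasing).
    """
    report = CurationReport()
    report.record("input", len(records))

    current = filter_evidence(records, config.min_evidence)
    report.record("evidence", len(current))

    current = filter_length(current, config.min_length, config.max_length)
    report.record("length", len(current))

    n_before = len(current)
    conflicted = dual_class_sequences(current)
    current = [r for r in current if r.sequence not in conflicted]
    report.removed_dual_class = len(conflicted)
    report.record("dual_class", len(current))

    if config.require_organism:
        current = filter_organism(current)
    report.record("organism", len(current))

    current, red_report = remove_redundancy(current, config.similarity_threshold)
    report.clusters_formed = red_report.clusters_formed
    report.record("redundancy", len(current))

    if not current:
        return [], [], report
    try:
        train, test = stratified_split(current, config.test_fraction, config.seed)
    except ValueError:
        # degenerate survivor set (single-member class): return all as train
        train, test = list(current), []
    report.record("train", len(train))
    return train, test, report
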