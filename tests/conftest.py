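"""Shared fixtures: tiny hand-built datasets and independent oracles."""

from fractions import Fraction

import numpy as np
import pytest

from epitopekit import LabelingScheme, PeptideRecord, SignatureConfig


@pytest.fixture(scope="session")
def physchem_scheme():
    return LabelingScheme.physicochemical()


@pytest.fixture(scope="session")
def physchem_config(physchem_scheme):
    """Physicochemical-only signature config with a small cutoff grid."""
    return SignatureConfig(schemes=[physchem_scheme], cutoffs=tuple(range(1, 6)))


def brute_force_signature(sequence, scheme, cutoffs, mode="cumulative"):
    """Independent signature oracle: enumerate every index pair, bin by
    (unordered label pair, separation), then accumulate per the mode."""
    labels = [scheme.assign[aa] for aa in sequence]
    order = {lab: i for i, lab in enumerate(scheme.labels)}
    by_pair_d = {}
    for i in range(len(sequence)):
        for j in range(i + 1, len(sequence)):
            a, b = labels[i], labels[j]
            key = (a, b) if order[a] <= order[b] else (b, a)
            by_pair_d[(key, j - i)] = by_pair_d.get((key, j - i), 0) + 1
    pairs = [(scheme.labels[i], scheme.labels[j])
             for i in range(len(scheme.labels))
             for j in range(i, len(scheme.labels))]
    out = {}
    for d in cutoffs:
        for p in pairs:
            exact = by_pair_d.get((p, d), 0)
            cum = sum(by_pair_d.get((p, dd), 0) for dd in range(1, d + 1))
            if mode == "cumulative":
                out[f"{p[0]}:{p[1]}-{d}"] = cum
            elif mode == "non_cumulative":
                out[f"{p[0]}:{p[1]}-{d}"] = exact
            else:  # both
                out[f"{p[0]}:{p[1]}-{d}"] = cum
                out[f"{p[0]}:{p[1]}-{d}~nc"] = exact
    return out


def mcc_oracle(tp, fp, tn, fn):
    """Exact-arithmetic MCC with the zero-factor convention."""
    denom = (
        Fraction(tp + fp) * Fraction(tp + fn)
        * Fraction(tn + fp) * Fraction(tn + fn)
    )
    if denom == 0:
        return 0.0
    return float(Fraction(tp * tn - fp * fn) / Fraction(float(denom) ** 0.5))


def auc_pair_counting_oracle(labels, scores):
    """Exhaustive concordant-pair AUC: ties between classes get half credit."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        return None
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def curation_fixture_records():
    """20 records crafted so each pipeline step removes exactly 2.

    evidence (-2) -> length (-2) -> dual-class (-2) -> organism (-2) ->
    redundancy at 0.95 (-2); survivor counts [20,18,16,14,12,10].
    """
    recs = [
        # removed by the evidence filter (< 2 assays)
        PeptideRecord("e1", "MKTAYIAK", "epitope", "Riboviria", 1),
        PeptideRecord("e2", "GQETWWNH", "non_epitope", "Sar", 1),
        # removed by the length filter
        PeptideRecord("l1", "ACDEF", "epitope", "Riboviria", 3),
        PeptideRecord("l2", "A" * 13 + "C" * 13, "non_epitope", "Discoba", 2),
        # removed by dual-class removal (same sequence, both classes)
        PeptideRecord("d1", "ACDEFGHIKL", "epitope", "Riboviria", 2),
        PeptideRecord("d2", "ACDEFGHIKL", "non_epitope", "Sar", 2),
        # removed by the organism requirement
        PeptideRecord("o1", "WYHKNQRSTV", "epitope", "unknown", 2),
        PeptideRecord("o2", "PLMGASTCDE", "non_epitope", "unknown", 3),
        # redundancy: one exact duplicate per class
        PeptideRecord("r1", "FFFFWWWWYY", "epitope", "Riboviria", 2),
        PeptideRecord("r2", "FFFFWWWWYY", "epitope", "Riboviria", 2),
        PeptideRecord("r3", "HHHHKKKKRR", "non_epitope", "Sar", 2),
        PeptideRecord("r4", "HHHHKKKKRR", "non_epitope", "Proteobacteria", 3),
        # mutually dissimilar survivors
        PeptideRecord("f1", "AAAAGGGGMM", "epitope", "Riboviria", 2),
        PeptideRecord("f2", "CCCCSSSSNN", "epitope", "Opisthokonta", 4),
        PeptideRecord("f3", "DDDDEEEEQQ", "epitope", "Viridiplantae", 2),
        PeptideRecord("f4", "MMMMPPPPVV", "non_epitope", "Riboviria", 2),
        PeptideRecord("f5", "TTTTNNNNCC", "non_epitope", "Discoba", 3),
        PeptideRecord("f6", "KKKKHHHHRR", "non_epitope", "Sar", 2),
        PeptideRecord("f7", "EEEEDDDDAA", "non_epitope", "Proteobacteria", 5),
        PeptideRecord("f8", "VVVVLLLLII", "non_epitope", "Opisthokonta", 2),
    ]
    assert len(recs) == 20
    return recs


@pytest.fixture
def curation_fixture():
    return curation_fixture_records()
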