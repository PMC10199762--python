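"""Synthetic IEDB-like peptide tables with controllable planted signal.

Generates labeled peptide records that emulate an experimental linear
B-cell epitope export: peptides of length 6-25, epitope:non-epitope
ratio ~1:6, organism classes drawn from the 20-class lineage vocabulary,
small-integer assay evidence counts (including values below 2 so the
evidence filter is exercised), and an optional planted 3-mer motif that
separates the classes.  The planted motif makes the discrimination
problem exactly analyzable: with a uniform residue background each
specific triplet occurs by chance at rate 20^-3 per position, so a motif
planted in epitopes at any appreciable rate dominates the fitted AAT
scale.

Every output is reproducible under the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np

from .io_formats import CANONICAL_AA, PeptideRecord, TAXONOMY_CLASSES


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic benchmark generator.

    Defaults emulate the curated-benchmark conditions: lengths 6-25,
    class ratio 1:6, a single planted triplet carried by 90% of epitopes,
    uniform residue background.
    """

    n_epitopes: int = 300
    n_non_epitopes: int = 1800
    min_length: int = 6
    max_length: int = 25
    motif: str = "WRY"
    motif_rate: float = 0.9
    background: Optional[Dict[str, float]] = None  # residue -> probability
    organism_bias: Optional[Dict[str, float]] = None  # class -> epitope weight
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.motif) != 3:
            raise ValueError("motif must be a 3-letter triplet")
        if any(ch not in CANONICAL_AA for ch in self.motif):
            raise ValueError(f"motif {self.motif!r} contains non-canonical residues")
        if not (0.0 <= self.motif_rate <= 1.0):
            raise ValueError("motif_rate must lie in [0, 1]")
        if self.min_length > self.max_length:
            raise ValueError("min_length must be <= max_length")
        if len(self.motif) > self.min_length:
            raise ValueError("motif longer than the minimum peptide length")

    def to_dict(self) -> dict:
        return {
            "n_epitopes": self.n_epitopes,
            "n_non_epitopes": self.n_non_epitopes,
            "min_length": self.min_length,
            "max_length": self.max_length,
            "motif": self.motif,
            "motif_rate": self.motif_rate,
            "background": self.background,
            "organism_bias": self.organism_bias,
            "seed": self.seed,
        }


def _background_probs(spec: SyntheticSpec) -> np.ndarray:
    if spec.background is None:
        return np.full(20, 1.0 / 20)
    probs = np.array([spec.background.get(aa, 0.0) for aa in CANONICAL_AA])
    total = probs.sum()
    if total <= 0:
        raise ValueError("background distribution has no mass on canonical residues")
    return probs / total


def _random_sequence(rng: np.random.Generator, length: int,
                     probs: np.ndarray) -> str:
    idx = rng.choice(20, size=length, p=probs)
    return "".join(CANONICAL_AA[i] for i in idx)


def generate(spec: SyntheticSpec) -> List[PeptideRecord]:
    """Generate a labeled synthetic peptide table.

    Epitopes carry the planted motif (overwritten at a random position)
    with probability ``motif_rate``; non-epitopes are pure background, so
    the motif appears in them only at the chance rate.  Evidence counts
    are uniform over 1..5; organism classes are uniform over the 20-class
    vocabulary unless ``organism_bias`` reweights the epitope class.
    """
    rng = np.random.default_rng(spec.seed)
    probs = _background_probs(spec)
    classes = list(TAXONOMY_CLASSES)
    if spec.organism_bias:
        unknown = sorted(set(spec.organism_bias) - set(classes))
        if unknown:
            raise ValueError(f"organism_bias names unknown classes: {unknown}")
        epi_w = np.array([spec.organism_bias.get(c, 1.0) for c in classes])
        epi_w = epi_w / epi_w.sum()
    else:
        epi_w = np.full(len(classes), 1.0 / len(classes))
    uni_w = np.full(len(classes), 1.0 / len(classes))

    records: List[PeptideRecord] = []
    for label, n, org_w, prefix in (
        ("epitope", spec.n_epitopes, epi_w, "epi"),
        ("non_epitope", spec.n_non_epitopes, uni_w, "non"),
    ):
        for i in range(n):
            length = int(rng.integers(spec.min_length, spec.max_length + 1))
            seq = _random_sequence(rng, length, probs)
            if label == "epitope" and rng.random() < spec.motif_rate:
                pos = int(rng.integers(0, length - len(spec.motif) + 1))
                seq = seq[:pos] + spec.motif + seq[pos + len(spec.motif):]
            records.append(
                PeptideRecord(
                    id=f"{prefix}_{i:05d}",
                    sequence=seq,
                    label=label,
                    organism_class=classes[int(rng.choice(len(classes), p=org_w))],
                    evidence_count=int(rng.integers(1, 6)),
                )
            )
    return records


def generate_conflicts(spec: SyntheticSpec, k: int) -> List[PeptideRecord]:
    """A clean base set plus exactly ``k`` dual-class conflict sequences.

    Each conflict sequence is drawn disjoint from the base sequences and
    appended once per class, so curation's dual-class filter removes
    exactly ``2k`` records (``k`` sequences).  ``k=0`` returns the base
    unchanged.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    base = generate(spec)
    if k == 0:
        return base
    rng = np.random.default_rng(spec.seed + 1)
    probs = _background_probs(spec)
    existing = {r.sequence for r in base}
    conflicts: List[PeptideRecord] = []
    made = 0
    while made < k:
        length = int(rng.integers(spec.min_length, spec.max_length + 1))
        seq = _random_sequence(rng, length, probs)
        if seq in existing:
            continue
        existing.add(seq)
        for label, prefix in (("epitope", "cepi"), ("non_epitope", "cnon")):
            conflicts.append(
                PeptideRecord(
                    id=f"{prefix}_{made:05d}",
                    sequence=seq,
                    label=label,
                    organism_class=TAXONOMY_CLASSES[
                        int(rng.integers(0, len(TAXONOMY_CLASSES)))
                    ],
                    evidence_count=int(rng.integers(2, 6)),
                )
            )
        made += 1
    return base + conflicts
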