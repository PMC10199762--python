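"""Non-signature peptide descriptors.

Four feature families besides the graph-based signatures:

* **AAT antigenicity ratio** — a per-triplet (3-mer) log-odds scale fitted
  on a training set, measuring how overrepresented each amino-acid
  triplet is in the epitope class; a peptide is summarized by the max,
  min, sum and mean of its overlapping-triplet scores (AAT_max, AAT_min,
  AAT_sum, AAT_mean).
* **CTD** — Composition / Transition / Distribution descriptors over
  3-group physicochemical property partitions (hydrophobicity,
  normalized van der Waals volume, polarity, charge, secondary structure,
  solvent accessibility by default; polarizability available).
* **Propensity-scale profiles** — mean/max/min of per-residue propensity
  values (Parker hydrophilicity, Chou-Fasman beta-turn, Emini surface
  accessibility, Kolaskar-Tongaonkar antigenicity).  Peptides are short,
  so single-residue values are used without window smoothing.
* **Taxonomy one-hot** — positional encoding of the source organism over
  the fixed 20-class lineage vocabulary; "unknown" encodes as all zeros.

:func:`featurize` concatenates the enabled families in a fixed order into
a :class:`~epitopekit.io_formats.FeatureMatrix`.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from math import log
from pathlib import Path
from typing import Dict, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    CANONICAL_AA,
    FeatureMatrix,
    PeptideRecord,
    TaxonomyVocabulary,
    validate_sequence,
)
from .signatures import SignatureConfig, signature, signature_feature_names

logger = logging.getLogger("epitopekit")

N_TRIPLETS = 20 ** 3  # 8000 possible canonical amino-acid triplets


def _load_propensity_scales() -> Dict[str, Dict[str, float]]:
    with resources.files("epitopekit.data").joinpath("propensity_scales.csv").open() as fh:
        df = pd.read_csv(fh)
    scales: Dict[str, Dict[str, float]] = {}
    for scale, sub in df.groupby("scale"):
        scales[scale] = dict(zip(sub["residue"], sub["value"].astype(float)))
    return scales


def _load_ctd_groups() -> Dict[str, Dict[str, str]]:
    with resources.files("epitopekit.data").joinpath("ctd_groups.csv").open() as fh:
        df = pd.read_csv(fh)
    groupings: Dict[str, Dict[str, str]] = {}
    for prop, sub in df.groupby("property"):
        assign: Dict[str, str] = {}
        for _, row in sub.iterrows():
            for aa in row["residues"]:
                assign[aa] = row["group"]
        groupings[prop] = assign
    return groupings


#: Per-residue propensity value tables, keyed by scale name.
PROPENSITY_SCALES: Dict[str, Dict[str, float]] = _load_propensity_scales()

#: Residue -> group (G1/G2/G3) assignment per physicochemical property.
CTD_GROUP_TABLES: Dict[str, Dict[str, str]] = _load_ctd_groups()

#: Properties enabled by default (polarizability is available but off).
DEFAULT_CTD_PROPERTIES = (
    "hydrophobicity",
    "normalized_vdw",
    "polarity",
    "secondary_structure",
    "solvent_accessibility",
    "charge",
)

DEFAULT_PROFILE_SCALES = (
    "parker_hydrophilicity",
    "choufasman_beta_turn",
    "emini_accessibility",
    "kolaskar_antigenicity",
)


@dataclass(frozen=True)
class CTDGrouping:
    """A 3-group partition of the 20 residues for one property."""

    property_name: str
    assign: Mapping[str, str]

    def __post_init__(self) -> None:
        missing = [aa for aa in CANONICAL_AA if aa not in self.assign]
        if missing:
            raise ValueError(
                f"CTD grouping {self.property_name!r} missing residues {missing}"
            )
        bad = sorted(set(self.assign.values()) - {"G1", "G2", "G3"})
        if bad:
            raise ValueError(f"CTD grouping {self.property_name!r}: bad groups {bad}")


def default_ctd_groupings(properties: Sequence[str] = DEFAULT_CTD_PROPERTIES) -> list:
    out = []
    for prop in properties:
        if prop not in CTD_GROUP_TABLES:
            raise KeyError(
                f"unknown CTD property {prop!r}; available: {sorted(CTD_GROUP_TABLES)}"
            )
        out.append(CTDGrouping(prop, CTD_GROUP_TABLES[prop]))
    return out


# ---------------------------------------------------------------------------
# AAT antigenicity-ratio scale
# ---------------------------------------------------------------------------

def dataset_fingerprint(sequences: Iterable[str]) -> str:
    """Order-independent sha256 fingerprint of a sequence multiset."""
    h = hashlib.sha256()
    for seq in sorted(sequences):
        h.update(seq.encode())
        h.update(b"\n")
    return h.hexdigest()


class FingerprintMismatch(ValueError):
    """An AAT scale is being used against data it was not fitted on."""


@dataclass
class AATScale:
    """Fitted amino-acid-triplet antigenicity-ratio score table.

    ``scores[t]`` is the pseudocount-smoothed, frequency-normalized
    log-odds of triplet ``t`` appearing in the epitope versus the
    non-epitope class; positive scores mark epitope-enriched triplets.
    Triplets unseen during fitting take ``default_score`` (0: no evidence
    either way).  ``fitted_on`` fingerprints the training sequences so
    train/test hygiene can be enforced downstream.
    """

    scores: Dict[str, float]
    pseudocount: float
    fitted_on: str = ""
    default_score: float = 0.0

    def __post_init__(self) -> None:
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        if len(self.scores) > N_TRIPLETS:
            raise ValueError("more triplet scores than possible triplets")

    def score(self, triplet: str) -> float:
        return self.scores.get(triplet, self.default_score)

    def assert_fitted_on(self, sequences: Iterable[str]) -> None:
        """Raise :class:`FingerprintMismatch` unless ``sequences`` is
        exactly the multiset this scale was fitted on."""
        fp = dataset_fingerprint(sequences)
        if fp != self.fitted_on:
            raise FingerprintMismatch(
                "AAT scale fingerprint does not match these sequences; "
                "the scale must be fitted on the training split only"
            )

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "format": "epitopekit.aat_scale/1",
                    "pseudocount": self.pseudocount,
                    "fitted_on": self.fitted_on,
                    "default_score": self.default_score,
                    "scores": self.scores,
                },
                sort_keys=True,
            )
        )

    @classmethod
    def from_json(cls, path) -> "AATScale":
        obj = json.loads(Path(path).read_text())
        return cls(
            scores=obj["scores"],
            pseudocount=obj["pseudocount"],
            fitted_on=obj["fitted_on"],
            default_score=obj["default_score"],
        )


def _triplets(sequence: str) -> list:
    return [sequence[i:i + 3] for i in range(len(sequence) - 2)]


def fit_aat_scale(epitope_sequences: Sequence[str],
                  non_epitope_sequences: Sequence[str],
                  pseudocount: float = 1.0) -> AATScale:
    """Fit the AAT antigenicity-ratio scale on two classes of sequences.

    For each triplet ``t`` observed in either class::

        score(t) = ln((c_epi(t) + a) / (c_non(t) + a))
                 + ln((N_non + a*8000) / (N_epi + a*8000))

    with overlapping-triplet counts ``c``, per-class totals ``N``, and
    pseudocount ``a``.  The second term normalizes for class size, so the
    score is a frequency log-odds; swapping the classes negates every
    score.  Sequences shorter than 3 are skipped with a warning.
    """
    if not epitope_sequences or not non_epitope_sequences:
        raise ValueError("both sequence sets must be non-empty")

    def count(seqs: Sequence[str]) -> Dict[str, int]:
        counts: Dict[str, int] = {}
        for s in seqs:
            if len(s) < 3:
                warnings.warn(f"sequence {s!r} shorter than 3, skipped in AAT fit")
                continue
            for t in _triplets(s):
                counts[t] = counts.get(t, 0) + 1
        return counts

    c_epi = count(epitope_sequences)
    c_non = count(non_epitope_sequences)
    n_epi = sum(c_epi.values())
    n_non = sum(c_non.values())
    a = float(pseudocount)
    norm = log((n_non + a * N_TRIPLETS) / (n_epi + a * N_TRIPLETS))
    scores = {
        t: log((c_epi.get(t, 0) + a) / (c_non.get(t, 0) + a)) + norm
        for t in set(c_epi) | set(c_non)
    }
    fp = dataset_fingerprint(list(epitope_sequences) + list(non_epitope_sequences))
    return AATScale(scores=scores, pseudocount=a, fitted_on=fp)


def aat_features(sequence: str, scale: AATScale) -> Dict[str, float]:
    """AAT summary features of a peptide: max, min, sum and mean of the
    scores of its overlapping triplets (unseen triplets score
    ``scale.default_score``)."""
    seq = validate_sequence(sequence)
    if len(seq) < 3:
        raise ValueError(f"sequence {seq!r} shorter than 3: no triplets")
    vals = np.array([scale.score(t) for t in _triplets(seq)])
    return {
        "AAT_max": float(vals.max()),
        "AAT_min": float(vals.min()),
        "AAT_sum": float(vals.sum()),
        "AAT_mean": float(vals.mean()),
    }


# ---------------------------------------------------------------------------
# CTD
# ---------------------------------------------------------------------------

_TRANSITION_PAIRS = (("G1", "G2"), ("G1", "G3"), ("G2", "G3"))
_DIST_QUANTILES = (("first", 0.0), ("p25", 0.25), ("p50", 0.50),
                   ("p75", 0.75), ("p100", 1.0))


def ctd_features(sequence: str,
                 groupings: Sequence[CTDGrouping] | None = None) -> Dict[str, float]:
    """Composition/Transition/Distribution features per property.

    Per property (21 values): composition = fraction of residues in each
    of G1..G3; transition = fraction of adjacent residue pairs crossing
    each unordered group pair; distribution = position (as % of sequence
    length, 1-based) of the first, 25%, 50%, 75% and last occurrence of
    each group.  A group absent from the sequence contributes 0 for all
    its distribution entries (fixed-length convention).

    Composition names follow ``<property>.G<k>`` (e.g. ``charge.G3`` =
    fraction of negatively charged residues).
    """
    seq = validate_sequence(sequence)
    if len(seq) < 2:
        raise ValueError("CTD transitions need sequence length >= 2")
    if groupings is None:
        groupings = default_ctd_groupings()
    L = len(seq)
    out: Dict[str, float] = {}
    for grouping in groupings:
        prop = grouping.property_name
        groups = [grouping.assign[aa] for aa in seq]
        # composition
        for g in ("G1", "G2", "G3"):
            out[f"{prop}.{g}"] = groups.count(g) / L
        # transition
        n_adj = L - 1
        for ga, gb in _TRANSITION_PAIRS:
            n_cross = sum(
                1 for x, y in zip(groups, groups[1:])
                if {x, y} == {ga, gb}
            )
            out[f"{prop}.T.{ga}{gb}"] = n_cross / n_adj
        # distribution
        for g in ("G1", "G2", "G3"):
            positions = [i + 1 for i, x in enumerate(groups) if x == g]
            for qname, q in _DIST_QUANTILES:
                if not positions:
                    out[f"{prop}.D.{g}.{qname}"] = 0.0
                else:
                    k = max(1, int(np.ceil(q * len(positions))))
                    out[f"{prop}.D.{g}.{qname}"] = positions[k - 1] / L * 100.0
    return out


def ctd_feature_names(groupings: Sequence[CTDGrouping] | None = None) -> list:
    if groupings is None:
        groupings = default_ctd_groupings()
    names = []
    for grouping in groupings:
        prop = grouping.property_name
        names += [f"{prop}.{g}" for g in ("G1", "G2", "G3")]
        names += [f"{prop}.T.{ga}{gb}" for ga, gb in _TRANSITION_PAIRS]
        names += [
            f"{prop}.D.{g}.{qname}"
            for g in ("G1", "G2", "G3")
            for qname, _ in _DIST_QUANTILES
        ]
    return names


# ---------------------------------------------------------------------------
# Propensity profiles and taxonomy
# ---------------------------------------------------------------------------

def scale_profile_features(sequence: str, scale_name: str) -> Dict[str, float]:
    """Mean/max/min of per-residue propensity values under a named scale."""
    if scale_name not in PROPENSITY_SCALES:
        raise KeyError(
            f"unknown scale {scale_name!r}; available: {sorted(PROPENSITY_SCALES)}"
        )
    seq = validate_sequence(sequence)
    table = PROPENSITY_SCALES[scale_name]
    vals = np.array([table[aa] for aa in seq])
    return {
        f"{scale_name}_mean": float(vals.mean()),
        f"{scale_name}_max": float(vals.max()),
        f"{scale_name}_min": float(vals.min()),
    }


def taxonomy_onehot(organism_class: str,
                    vocab: TaxonomyVocabulary | None = None) -> np.ndarray:
    """Positional one-hot over the 20-class lineage vocabulary.

    ``"unknown"`` encodes as the all-zero vector; any other unlisted name
    is an error.
    """
    if vocab is None:
        vocab = TaxonomyVocabulary()
    vec = np.zeros(len(vocab.classes), dtype=float)
    if organism_class == "unknown":
        return vec
    if organism_class not in vocab:
        raise KeyError(
            f"organism class {organism_class!r} not in taxonomy vocabulary"
        )
    vec[vocab.index(organism_class)] = 1.0
    return vec


# ---------------------------------------------------------------------------
# Full featurization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeaturizeOptions:
    """Which descriptor families to include and their sub-configuration."""

    signatures: bool = True
    aat: bool = True
    ctd: bool = True
    profiles: bool = True
    taxonomy: bool = True
    ctd_properties: tuple = DEFAULT_CTD_PROPERTIES
    profile_scales: tuple = DEFAULT_PROFILE_SCALES


def featurize(records: Sequence[PeptideRecord],
              aat_scale: AATScale | None = None,
              signature_config: SignatureConfig | None = None,
              options: FeaturizeOptions = FeaturizeOptions(),
              vocab: TaxonomyVocabulary | None = None) -> FeatureMatrix:
    """Build the full feature matrix for a set of peptides.

    Column order is fixed given the configuration: graph-based signatures,
    AAT summaries, CTD, propensity profiles, taxonomy one-hot.  The AAT
    scale must already be fitted (on training data only); featurization
    never refits it.  A pure function of (records, scale, config): the
    same inputs always produce the identical matrix.
    """
    if options.aat and aat_scale is None:
        raise ValueError("AAT features enabled but no fitted AATScale given")
    if options.signatures and signature_config is None:
        signature_config = SignatureConfig()
    if vocab is None:
        vocab = TaxonomyVocabulary()
    groupings = default_ctd_groupings(options.ctd_properties) if options.ctd else []

    ids = [r.id for r in records]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate record ids; featurization needs unique ids")

    columns: list = []
    provenance: Dict[str, str] = {}
    if options.signatures:
        sig_names = signature_feature_names(signature_config)
        columns += sig_names
        provenance.update({n: "signatures" for n in sig_names})
    if options.aat:
        aat_names = ["AAT_max", "AAT_min", "AAT_sum", "AAT_mean"]
        columns += aat_names
        provenance.update({n: "aat" for n in aat_names})
    if options.ctd:
        names = ctd_feature_names(groupings)
        columns += names
        provenance.update({n: "ctd" for n in names})
    if options.profiles:
        for s in options.profile_scales:
            names = [f"{s}_mean", f"{s}_max", f"{s}_min"]
            columns += names
            provenance.update({n: "profiles" for n in names})
    if options.taxonomy:
        tax_names = [f"taxonomy.{c.replace(' ', '_')}" for c in vocab.classes]
        columns += tax_names
        provenance.update({n: "taxonomy" for n in tax_names})

    rows = np.empty((len(records), len(columns)), dtype=float)
    for row_i, rec in enumerate(records):
        vals: list = []
        try:
            if options.signatures:
                sig = signature(rec.sequence, signature_config)
                vals += list(sig.values())
            if options.aat:
                feats = aat_features(rec.sequence, aat_scale)
                vals += [feats[n] for n in ("AAT_max", "AAT_min", "AAT_sum", "AAT_mean")]
            if options.ctd:
                feats = ctd_features(rec.sequence, groupings)
                vals += list(feats.values())
            if options.profiles:
                for s in options.profile_scales:
                    feats = scale_profile_features(rec.sequence, s)
                    vals += [feats[f"{s}_mean"], feats[f"{s}_max"], feats[f"{s}_min"]]
            if options.taxonomy:
                vals += list(taxonomy_onehot(rec.organism_class, vocab))
        except (ValueError, KeyError) as exc:
            raise ValueError(f"record {rec.id!r}: {exc}") from exc
        rows[row_i, :] = vals

    df = pd.DataFrame(rows, index=pd.Index(ids, name="id"), columns=columns)
    return FeatureMatrix(data=df, provenance=provenance)
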