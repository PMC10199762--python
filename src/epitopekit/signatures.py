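"""Graph-based sequence signatures for linear peptides.

A peptide is viewed as a path graph whose nodes (residues) carry
categorical labels.  For each sequence-distance cutoff ``d`` the signature
counts, per unordered label pair, the residue pairs separated by exactly
``d`` positions (non-cumulative) or by at most ``d`` positions
(cumulative).  Two labeling families are supported:

* categorical physicochemical classes (Acidic, Apolar, Aromatic, Basic,
  PolarNeutral), and
* binary High/Low labels derived from a per-residue propensity scale
  (hydrophilicity, beta-turn, surface accessibility, antigenicity)
  thresholded at the scale's unweighted mean over the 20 residues.

Feature names follow the grammar ``LabelA:LabelB-d[~scheme][~nc]`` with
LabelA <= LabelB in the scheme's label order, e.g. ``Apolar:Aromatic-8``
= pairs of apolar and aromatic residues within sequence distance 8
(cumulative, physicochemical scheme).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, Mapping, Sequence, Tuple

import numpy as np

from .io_formats import CANONICAL_AA, validate_sequence

#: Physicochemical class assignment (pharmacophore-style five-class table).
PHYSICOCHEMICAL_CLASSES: Dict[str, str] = {}
for _res in "AGILMPV":
    PHYSICOCHEMICAL_CLASSES[_res] = "Apolar"
for _res in "FWY":
    PHYSICOCHEMICAL_CLASSES[_res] = "Aromatic"
for _res in "CNQST":
    PHYSICOCHEMICAL_CLASSES[_res] = "PolarNeutral"
for _res in "DE":
    PHYSICOCHEMICAL_CLASSES[_res] = "Acidic"
for _res in "HKR":
    PHYSICOCHEMICAL_CLASSES[_res] = "Basic"

#: Label order is alphabetical; pair names are canonicalized against it
#: ("Acidic:Apolar", never "Apolar:Acidic").
PHYSICOCHEMICAL_LABELS = ("Acidic", "Apolar", "Aromatic", "Basic", "PolarNeutral")


@dataclass(frozen=True)
class LabelingScheme:
    """A total mapping from residue to categorical node label.

    ``kind`` is ``categorical`` (e.g. physicochemical classes) or
    ``scale_binary`` (High/Low at a threshold on a numeric propensity
    scale).
    """

    name: str
    kind: str
    assign: Mapping[str, str]
    labels: Tuple[str, ...]

    def __post_init__(self) -> None:
        if self.kind not in ("categorical", "scale_binary"):
            raise ValueError(f"unknown scheme kind {self.kind!r}")
        missing = [aa for aa in CANONICAL_AA if aa not in self.assign]
        if missing:
            raise ValueError(f"scheme {self.name!r} missing residues {missing}")
        bad = sorted(set(self.assign.values()) - set(self.labels))
        if bad:
            raise ValueError(f"scheme {self.name!r} assigns unlisted labels {bad}")

    @classmethod
    def physicochemical(cls) -> "LabelingScheme":
        return cls(
            name="physchem",
            kind="categorical",
            assign=dict(PHYSICOCHEMICAL_CLASSES),
            labels=PHYSICOCHEMICAL_LABELS,
        )

    @classmethod
    def from_scale(cls, name: str, values: Mapping[str, float],
                   threshold: float | None = None) -> "LabelingScheme":
        """Binary High/Low scheme from a per-residue numeric scale.

        ``threshold`` defaults to the unweighted mean of the 20 values;
        residues with value > threshold are High, the rest Low.
        """
        missing = [aa for aa in CANONICAL_AA if aa not in values]
        if missing:
            raise ValueError(f"scale {name!r} missing residues {missing}")
        if threshold is None:
            threshold = float(np.mean([values[aa] for aa in CANONICAL_AA]))
        assign = {
            aa: ("High" if values[aa] > threshold else "Low")
            for aa in CANONICAL_AA
        }
        return cls(name=name, kind="scale_binary", assign=assign,
                   labels=("High", "Low"))


def default_schemes() -> list:
    """Physicochemical classes plus the four propensity-scale binarizations."""
    from .descriptors import PROPENSITY_SCALES

    schemes = [LabelingScheme.physicochemical()]
    for scale_name in ("parker_hydrophilicity", "choufasman_beta_turn",
                      "emini_accessibility", "kolaskar_antigenicity"):
        schemes.append(
            LabelingScheme.from_scale(scale_name, PROPENSITY_SCALES[scale_name])
        )
    return schemes


@dataclass(frozen=True)
class SignatureConfig:
    """Schemes, distance cutoffs and accumulation mode for signatures.

    Default cutoffs 1..24 cover every residue separation possible in a
    25-mer; default mode is cumulative.
    """

    schemes: tuple = None  # type: ignore[assignment]
    cutoffs: tuple = tuple(range(1, 25))
    mode: str = "cumulative"

    def __post_init__(self) -> None:
        if self.schemes is None:
            object.__setattr__(self, "schemes", tuple(default_schemes()))
        else:
            object.__setattr__(self, "schemes", tuple(self.schemes))
        object.__setattr__(self, "cutoffs", tuple(int(c) for c in self.cutoffs))
        if not self.cutoffs or any(c < 1 for c in self.cutoffs):
            raise ValueError("cutoffs must be positive integers")
        if any(b <= a for a, b in zip(self.cutoffs, self.cutoffs[1:])):
            raise ValueError("cutoffs must be strictly increasing")
        if self.mode not in ("cumulative", "non_cumulative", "both"):
            raise ValueError(f"unknown mode {self.mode!r}")


def assign_labels(sequence: str, scheme: LabelingScheme) -> list:
    """Label every residue of a canonical sequence under ``scheme``."""
    seq = validate_sequence(sequence)
    return [scheme.assign[aa] for aa in seq]


def _pair_key(a: str, b: str, order: Mapping[str, int]) -> tuple:
    return (a, b) if order[a] <= order[b] else (b, a)


def pair_counts(labels: Sequence[str], d: int,
                label_order: Sequence[str] | None = None) -> dict:
    """Count residue pairs ``(i, i+d)`` per unordered label pair.

    ``d >= len(labels)`` yields an all-zero map (no such pairs exist);
    that is a documented degenerate case, not an error.
    """
    if d < 1:
        raise ValueError("distance d must be >= 1")
    if label_order is None:
        label_order = sorted(set(labels))
    order = {lab: i for i, lab in enumerate(label_order)}
    counts: dict = {}
    n = len(labels)
    for i in range(n - d):
        key = _pair_key(labels[i], labels[i + d], order)
        counts[key] = counts.get(key, 0) + 1
    return counts


def _scheme_pairs(scheme: LabelingScheme) -> list:
    labs = scheme.labels
    return [(labs[i], labs[j]) for i in range(len(labs))
            for j in range(i, len(labs))]


def feature_name(pair: tuple, d: int, scheme: LabelingScheme,
                 noncumulative: bool = False) -> str:
    """Canonical signature feature name, e.g. ``Apolar:Aromatic-8``.

    Non-default schemes append ``~<scheme>``; in ``both`` mode the
    non-cumulative copy appends ``~nc``.
    """
    name = f"{pair[0]}:{pair[1]}-{d}"
    if scheme.name != "physchem":
        name += f"~{scheme.name}"
    if noncumulative:
        name += "~nc"
    return name


def signature(sequence: str, config: SignatureConfig) -> dict:
    """Signature vector: ordered map of feature name -> non-negative count.

    Non-cumulative entries are the exact-distance pair counts at each
    cutoff; cumulative entries are running sums over all distances up to
    the cutoff.  Feature order is fixed given the config (schemes ->
    cutoffs -> pairs), so vectors from the same config are comparable.
    """
    seq = validate_sequence(sequence)
    if len(seq) < 2:
        raise ValueError(f"sequence {seq!r} shorter than 2 residues")

    out: dict = {}
    for scheme in config.schemes:
        labels = assign_labels(seq, scheme)
        order = {lab: i for i, lab in enumerate(scheme.labels)}
        pairs = _scheme_pairs(scheme)
        # exact-distance counts for every distance up to the largest cutoff
        max_d = config.cutoffs[-1]
        exact = {}  # d -> {pair: count}
        for d in range(1, max_d + 1):
            exact[d] = pair_counts(labels, d, scheme.labels) if d < len(labels) else {}
        running = {p: 0 for p in pairs}
        cum_at = {}  # cutoff -> {pair: cumulative count}
        ci = 0
        for d in range(1, max_d + 1):
            for p, c in exact[d].items():
                running[p] += c
            if ci < len(config.cutoffs) and d == config.cutoffs[ci]:
                cum_at[d] = dict(running)
                ci += 1
        for d in config.cutoffs:
            for p in pairs:
                if config.mode in ("cumulative", "both"):
                    out[feature_name(p, d, scheme)] = cum_at[d].get(p, 0)
                if config.mode == "non_cumulative":
                    out[feature_name(p, d, scheme)] = exact[d].get(p, 0)
                elif config.mode == "both":
                    out[feature_name(p, d, scheme, noncumulative=True)] = (
                        exact[d].get(p, 0)
                    )
    return out


def signature_feature_names(config: SignatureConfig) -> list:
    """The fixed feature-name order produced by :func:`signature`."""
    names: list = []
    for scheme in config.schemes:
        pairs = _scheme_pairs(scheme)
        for d in config.cutoffs:
            for p in pairs:
                if config.mode in ("cumulative", "both"):
                    names.append(feature_name(p, d, scheme))
                if config.mode == "non_cumulative":
                    names.append(feature_name(p, d, scheme))
                elif config.mode == "both":
                    names.append(feature_name(p, d, scheme, noncumulative=True))
    return names
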