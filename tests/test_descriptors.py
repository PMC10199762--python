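"""AAT scale fitting, CTD descriptors, profiles, taxonomy and featurize."""

import math

import numpy as np
import pytest

from epitopekit import (
    AATScale,
    FeaturizeOptions,
    FingerprintMismatch,
    PROPENSITY_SCALES,
    PeptideRecord,
    SignatureConfig,
    TaxonomyVocabulary,
    aat_features,
    ctd_features,
    featurize,
    fit_aat_scale,
    scale_profile_features,
    taxonomy_onehot,
)
from epitopekit.descriptors import (
    CTD_GROUP_TABLES,
    ctd_feature_names,
    default_ctd_groupings,
)
from epitopekit.signatures import LabelingScheme

AA = "ACDEFGHIKLMNPQRSTVWY"


def _random_peptides(rng, n, min_len=6, max_len=25):
    return ["".join(rng.choice(list(AA), size=int(rng.integers(min_len, max_len + 1))))
            for _ in range(n)]


class TestAATScale:
    def test_worked_toy_example(self):
        """epitopes={AAAA}, non={CCCC}: both classes contribute 2 triplets,
        so the class-size term vanishes and score(AAA) = ln 3."""
        scale = fit_aat_scale(["AAAA"], ["CCCC"], pseudocount=1.0)
        assert scale.scores["AAA"] == pytest.approx(math.log(3), abs=1e-12)
        assert scale.scores["CCC"] == pytest.approx(-math.log(3), abs=1e-12)

    def test_identical_classes_give_zero_scores(self):
        scale = fit_aat_scale(["ACDEFG", "WWYYHH"], ["ACDEFG", "WWYYHH"])
        assert all(abs(v) < 1e-12 for v in scale.scores.values())

    def test_class_swap_antisymmetry(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = _random_peptides(rng, 5)
            b = _random_peptides(rng, 5)
            fwd = fit_aat_scale(a, b)
            rev = fit_aat_scale(b, a)
            assert set(fwd.scores) == set(rev.scores)
            for t in fwd.scores:
                assert fwd.scores[t] == pytest.approx(-rev.scores[t], abs=1e-9)

    def test_shrinkage_to_zero_as_pseudocount_grows(self):
        small = fit_aat_scale(["AAAA"], ["CCCC"], pseudocount=1.0)
        large = fit_aat_scale(["AAAA"], ["CCCC"], pseudocount=1e6)
        assert abs(large.scores["AAA"]) < 1e-4 < abs(small.scores["AAA"])

    def test_too_short_sequences_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="shorter than 3"):
            scale = fit_aat_scale(["AAAA", "AC"], ["CCCC"])
        assert "AAA" in scale.scores

    def test_json_round_trip(self, tmp_path):
        scale = fit_aat_scale(["AAAA"], ["CCCC"])
        p = tmp_path / "scale.json"
        scale.to_json(p)
        back = AATScale.from_json(p)
        assert back.scores == scale.scores
        assert back.fitted_on == scale.fitted_on
        assert back.pseudocount == scale.pseudocount

    def test_fingerprint_guard(self):
        scale = fit_aat_scale(["AAAA"], ["CCCC"])
        scale.assert_fitted_on(["AAAA", "CCCC"])  # order-independent
        scale.assert_fitted_on(["CCCC", "AAAA"])
        with pytest.raises(FingerprintMismatch):
            scale.assert_fitted_on(["AAAA", "DDDD"])


class TestAATFeatures:
    def test_homogeneous_peptide_max_equals_min(self):
        scale = fit_aat_scale(["AAAA"], ["CCCC"])
        feats = aat_features("AAAA", scale)
        assert feats["AAT_max"] == feats["AAT_min"] == pytest.approx(math.log(3))
        assert feats["AAT_sum"] == pytest.approx(2 * math.log(3))

    def test_all_zero_scale_gives_zero_features(self):
        scale = AATScale(scores={}, pseudocount=1.0)
        feats = aat_features("ACDEFGHIKL", scale)
        assert all(v == 0.0 for v in feats.values())

    def test_max_at_least_min_always(self):
        rng = np.random.default_rng(1)
        scale = fit_aat_scale(_random_peptides(rng, 10), _random_peptides(rng, 10))
        for seq in _random_peptides(rng, 50):
            feats = aat_features(seq, scale)
            assert feats["AAT_max"] >= feats["AAT_mean"] >= feats["AAT_min"]

    def test_too_short_is_error(self):
        scale = AATScale(scores={}, pseudocount=1.0)
        with pytest.raises(ValueError):
            aat_features("AC", scale)


class TestCTD:
    def test_group_tables_partition_the_alphabet(self):
        for prop, assign in CTD_GROUP_TABLES.items():
            assert sorted(assign) == sorted(AA), prop
            assert set(assign.values()) <= {"G1", "G2", "G3"}

    def test_all_negative_peptide_under_charge(self):
        g = default_ctd_groupings(("charge",))
        feats = ctd_features("DDDD", g)
        assert feats["charge.G1"] == 0.0
        assert feats["charge.G2"] == 0.0
        assert feats["charge.G3"] == 1.0  # G3 = negatively charged (D, E)
        assert all(feats[f"charge.T.{p}"] == 0.0 for p in ("G1G2", "G1G3", "G2G3"))

    def test_alternating_charges_transition_fraction_one(self):
        g = default_ctd_groupings(("charge",))
        feats = ctd_features("DKDK", g)
        assert feats["charge.T.G1G3"] == 1.0  # all 3 adjacent pairs cross

    def test_composition_sums_to_one_per_property(self):
        rng = np.random.default_rng(2)
        groupings = default_ctd_groupings()
        for seq in _random_peptides(rng, 100):
            feats = ctd_features(seq, groupings)
            for grouping in groupings:
                prop = grouping.property_name
                total = sum(feats[f"{prop}.{g}"] for g in ("G1", "G2", "G3"))
                assert total == pytest.approx(1.0, abs=1e-12)

    def test_distribution_percentiles_non_decreasing(self):
        rng = np.random.default_rng(3)
        groupings = default_ctd_groupings()
        for seq in _random_peptides(rng, 100):
            feats = ctd_features(seq, groupings)
            for grouping in groupings:
                prop = grouping.property_name
                for g in ("G1", "G2", "G3"):
                    series = [feats[f"{prop}.D.{g}.{q}"]
                              for q in ("first", "p25", "p50", "p75", "p100")]
                    assert series == sorted(series)

    def test_transitions_lie_in_unit_interval(self):
        rng = np.random.default_rng(4)
        groupings = default_ctd_groupings()
        for seq in _random_peptides(rng, 50):
            feats = ctd_features(seq, groupings)
            for name, v in feats.items():
                if ".T." in name:
                    assert 0.0 <= v <= 1.0


class TestProfilesAndTaxonomy:
    def test_homopolymer_profile_collapses_to_residue_value(self):
        val = PROPENSITY_SCALES["parker_hydrophilicity"]["K"]
        feats = scale_profile_features("KKKKKK", "parker_hydrophilicity")
        assert feats["parker_hydrophilicity_mean"] == val
        assert feats["parker_hydrophilicity_max"] == val
        assert feats["parker_hydrophilicity_min"] == val

    def test_mean_invariant_under_reversal_and_ordering(self):
        seq = "ACDWYKKR"
        for scale in PROPENSITY_SCALES:
            f = scale_profile_features(seq, scale)
            r = scale_profile_features(seq[::-1], scale)
            assert f == r
            assert f[f"{scale}_max"] >= f[f"{scale}_mean"] >= f[f"{scale}_min"]

    def test_unknown_scale_error_lists_available(self):
        with pytest.raises(KeyError, match="parker_hydrophilicity"):
            scale_profile_features("ACDEFG", "nope")

    def test_onehot_known_class(self):
        vec = taxonomy_onehot("Riboviria")
        assert vec.sum() == 1.0 and vec[0] == 1.0

    def test_onehot_unknown_is_all_zero(self):
        assert taxonomy_onehot("unknown").sum() == 0.0

    def test_onehot_every_class_sums_to_one(self):
        vocab = TaxonomyVocabulary()
        for c in vocab.classes:
            assert taxonomy_onehot(c, vocab).sum() == 1.0

    def test_onehot_unlisted_class_is_error(self):
        with pytest.raises(KeyError):
            taxonomy_onehot("Martian")


class TestFeaturize:
    def _records(self):
        return [
            PeptideRecord("a", "ACDEFGWYHK", "epitope", "Riboviria", 2),
            PeptideRecord("b", "ACDEFGWYHK", "epitope", "Riboviria", 2),
            PeptideRecord("c", "KKKRRRHHHW", "non_epitope", "Sar", 3),
        ]

    def _scale(self):
        return fit_aat_scale(["ACDEFGWYHK"], ["KKKRRRHHHW"])

    def test_identical_records_give_identical_rows(self, physchem_config):
        m = featurize(self._records(), self._scale(), physchem_config)
        assert np.array_equal(m.data.loc["a"].to_numpy(),
                              m.data.loc["b"].to_numpy())

    def test_repeated_calls_byte_identical(self, physchem_config):
        m1 = featurize(self._records(), self._scale(), physchem_config)
        m2 = featurize(self._records(), self._scale(), physchem_config)
        assert m1.data.equals(m2.data)

    def test_disabling_taxonomy_drops_twenty_columns(self, physchem_config):
        full = featurize(self._records(), self._scale(), physchem_config)
        no_tax = featurize(self._records(), self._scale(), physchem_config,
                           FeaturizeOptions(taxonomy=False))
        assert len(full.feature_names) - len(no_tax.feature_names) == 20

    def test_expected_feature_names_present(self):
        cfg = SignatureConfig(
            schemes=[LabelingScheme.physicochemical()],
            cutoffs=tuple(range(1, 9)))
        m = featurize(self._records(), self._scale(), cfg)
        assert "AAT_max" in m.feature_names
        assert "Apolar:Aromatic-8" in m.feature_names
        assert "charge.G3" in m.feature_names
        assert m.provenance["AAT_max"] == "aat"
        assert m.provenance["Apolar:Aromatic-8"] == "signatures"

    def test_component_failure_names_the_record(self, physchem_config):
        recs = self._records() + [PeptideRecord("tiny", "ACDEF")]
        # 'tiny' has length 5 < minimum needed nowhere, but taxonomy of an
        # unlabeled record is fine; force an AAT failure with a 2-mer
        recs[-1] = PeptideRecord("tiny", "AC")
        with pytest.raises(ValueError, match="tiny"):
            featurize(recs, self._scale(), physchem_config)

    def test_duplicate_ids_rejected(self, physchem_config):
        recs = [PeptideRecord("a", "ACDEFG"), PeptideRecord("a", "WWYYHH")]
        with pytest.raises(ValueError, match="unique"):
            featurize(recs, self._scale(), physchem_config)

    def test_aat_enabled_requires_scale(self, physchem_config):
        with pytest.raises(ValueError, match="AATScale"):
            featurize(self._records(), None, physchem_config)
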