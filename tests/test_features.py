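import random
from collections import Counter

import pytest

from aee.corpus import Entity
from aee.features import (
    ConfigurationError,
    FeatureClassId,
    attached_edge_features,
    chain_features,
    content_features,
    edge_features,
    feature_size,
    linear_order_features,
    main_features,
    sentence_features,
    trigger_features,
)

from conftest import make_sentence, random_tree_sentence


def TC(spec):
    return FeatureClassId.parse("trigger", spec)


def EC(spec):
    return FeatureClassId.parse("edge", spec)


class TestFeatureClassId:
    def test_parse_variants(self):
        assert TC("4p").variant == "prime"
        assert TC("4'") == TC("4p")
        assert TC(3).variant == "base"
        assert str(TC("6p")) == "6'"

    def test_invalid_ids_rejected(self):
        with pytest.raises(ConfigurationError):
            FeatureClassId("trigger", 7)
        with pytest.raises(ConfigurationError):
            FeatureClassId("edge", 3)  # absorbed into the entity class
        with pytest.raises(ConfigurationError):
            FeatureClassId("trigger", 1, "prime")  # no variant defined


class TestSentenceFeatures:
    def test_bag_of_words_counting(self):
        sent = make_sentence(["NFAT1", "involves", "NFAT1"])
        assert sentence_features(sent) == Counter(
            {"class1:bow=nfat1": 2, "class1:bow=involves": 1}
        )

    def test_single_token(self):
        feats = sentence_features(make_sentence(["only"]))
        assert feats == Counter({"class1:bow=only": 1})

    @pytest.mark.parametrize("seed", range(5))
    def test_total_count_equals_sentence_length(self, seed):
        sent = random_tree_sentence(random.Random(seed), 9)
        assert sum(sentence_features(sent).values()) == 9


class TestMainFeatures:
    def test_binding_pos_stem_nonstem(self):
        sent = make_sentence(["binding"], pos=["NN"])
        assert main_features(sent, 0) == Counter(
            {"class2:pos=NN": 1, "class2:stem=bind": 1, "class2:nonstem=ing": 1}
        )

    def test_no_nonstem_when_stem_equals_text(self):
        sent = make_sentence(["cat"])
        feats = main_features(sent, 0)
        assert not any(k.startswith("class2:nonstem") for k in feats)

    @pytest.mark.parametrize("word", ["cat", "binding", "involves", "IL-4"])
    def test_count_is_two_or_three(self, word):
        feats = main_features(make_sentence([word]), 0)
        assert sum(feats.values()) in (2, 3)


class TestLinearOrderFeatures:
    def test_middle_token_window_one(self):
        sent = make_sentence(["a", "b", "c"], pos=["DT", "NN", "VB"])
        feats = linear_order_features(sent, 1, window=1)
        assert feats == Counter(
            {
                "class3:lin_-1_text=a": 1,
                "class3:lin_-1_pos=DT": 1,
                "class3:lin_+1_text=c": 1,
                "class3:lin_+1_pos=VB": 1,
            }
        )

    def test_first_token_has_no_negative_offsets(self):
        feats = linear_order_features(make_sentence(["a", "b"]), 0, window=2)
        assert not any("lin_-" in k for k in feats)

    @pytest.mark.parametrize("seed,window", [(0, 1), (1, 2), (2, 3)])
    def test_count_is_twice_neighbours_in_window(self, seed, window):
        rng = random.Random(seed)
        sent = random_tree_sentence(rng, 8)
        for t in range(8):
            neighbours = sum(
                1
                for off in range(-window, window + 1)
                if off != 0 and 0 <= t + off < 8
            )
            feats = linear_order_features(sent, t, window=window)
            assert sum(feats.values()) == 2 * neighbours

    def test_bad_window_rejected(self):
        with pytest.raises(ConfigurationError):
            linear_order_features(make_sentence(["a"]), 0, window=0)


class TestContentFeatures:
    def test_il4_base(self):
        feats = content_features(make_sentence(["IL-4"]), 0)
        assert feats == Counter(
            {
                "class4:upper=initial": 1,
                "class4:upper=all": 1,
                "class4:has=digit": 1,
                "class4:has=hyphen": 1,
                "class4:dt=il": 1,
                "class4:dt=l-": 1,
                "class4:dt=-4": 1,
                "class4:tt=il-": 1,
                "class4:tt=l-4": 1,
            }
        )

    def test_length_one_token_has_no_ngrams(self):
        feats = content_features(make_sentence(["x"]), 0, variant="prime")
        assert not any(f"class4:{r}" in k for k in feats for r in ("dt", "tt", "ft"))

    @pytest.mark.parametrize("word", ["gene", "binding", "phosphorylation"])
    def test_ft_count_is_length_minus_three(self, word):
        feats = content_features(make_sentence([word]), 0, variant="prime")
        n_ft = sum(c for k, c in feats.items() if k.startswith("class4:ft="))
        assert n_ft == len(word) - 3

    def test_prime_adds_only_ft(self):
        base = content_features(make_sentence(["binding"]), 0, variant="base")
        prime = content_features(make_sentence(["binding"]), 0, variant="prime")
        extra = prime - base
        assert base - prime == Counter()
        assert all(k.startswith("class4:ft=") for k in extra)


class TestAttachedEdgeFeatures:
    def test_isolated_token_empty(self):
        sent = make_sentence(["a", "b", "c"], edges=[(0, 1, "amod")])
        assert attached_edge_features(sent, 2) == Counter()

    def test_single_edge_four_features(self, chain_sentence):
        feats = attached_edge_features(chain_sentence, 0)
        assert feats == Counter(
            {
                "class5:rel=nsubj": 1,
                "class5:dir=dep": 1,
                "class5:nbr_text=involves": 1,
                "class5:nbr_pos=VBZ": 1,
            }
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_count_proportional_to_degree(self, seed):
        sent = random_tree_sentence(random.Random(seed), 8)
        for t in range(8):
            degree = sum(1 for e in sent.edges if t in (e.governor, e.dependent))
            assert sum(attached_edge_features(sent, t).values()) == 4 * degree


class TestChainFeatures:
    def test_chain_walks_depth_two(self, chain_sentence):
        feats = chain_features(chain_sentence, 0, depth=2)
        assert feats == Counter(
            {
                "class6:chain=<nsubj:involves": 1,
                "class6:chain=<nsubj.>dobj:il-4": 1,
            }
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_depth_one_matches_attached_edges(self, seed):
        sent = random_tree_sentence(random.Random(seed), 8)
        for t in range(8):
            chains = chain_features(sent, t, depth=1)
            rels = Counter()
            terms = Counter()
            for key, c in chains.items():
                walk, term = key.split("=", 1)[1].rsplit(":", 1)
                rels[walk[1:]] += c
                terms[term] += c
            attached = attached_edge_features(sent, t)
            assert rels == Counter(
                {k.split("=", 1)[1]: c for k, c in attached.items() if "rel=" in k}
            )
            assert terms == Counter(
                {k.split("=", 1)[1]: c for k, c in attached.items() if "nbr_text=" in k}
            )

    @pytest.mark.parametrize("seed", range(5))
    def test_prime_merge_never_adds(self, seed):
        sent = random_tree_sentence(random.Random(seed), 7)
        for t in range(7):
            prime = chain_features(sent, t, depth=2, variant="prime")
            combined = sum(
                (chain_features(sent, t, depth=2), attached_edge_features(sent, t)),
                Counter(),
            )
            assert sum(prime.values()) <= sum(combined.values())
            assert all(c == 1 for c in prime.values())

    def test_bad_depth_rejected(self, chain_sentence):
        with pytest.raises(ConfigurationError):
            chain_features(chain_sentence, 0, depth=0)


class TestEdgeFeatures:
    def test_adjacent_heads_pathlen_one(self, chain_sentence):
        e1 = chain_sentence.entity_by_id("e1")
        e0 = chain_sentence.entity_by_id("e0")
        feats = edge_features(chain_sentence, e1, e0, [EC(2)])
        assert feats == Counter({"class2:pathlen=1": 1})

    def test_same_head_degenerate(self, chain_sentence):
        e0 = chain_sentence.entity_by_id("e0")
        feats = edge_features(chain_sentence, e0, e0, [EC(2), EC(5)])
        assert feats == Counter({"class2:pathlen=0": 1})

    def test_prime_path_length_adds_bin(self, chain_sentence):
        e1 = chain_sentence.entity_by_id("e1")
        e0 = chain_sentence.entity_by_id("e0")
        feats = edge_features(chain_sentence, e1, e0, [EC("2p")])
        assert feats["class2:pathbin=1"] == 1

    @pytest.mark.parametrize("seed", range(5))
    def test_single_element_counting_oracle(self, seed):
        from aee.corpus import shortest_dependency_path

        sent = random_tree_sentence(random.Random(seed), 8)
        a = Entity(id="a", type="Protein", head=0, given=True)
        b = Entity(id="b", type="Protein", head=7, given=True)
        path = shortest_dependency_path(sent, 0, 7)
        feats = edge_features(sent, a, b, [EC(4)])
        assert sum(feats.values()) == len(path.token_indices) + len(path.steps)

    def test_sentence_class_prime_adds_pos_bow(self, chain_sentence):
        e1 = chain_sentence.entity_by_id("e1")
        e0 = chain_sentence.entity_by_id("e0")
        base = edge_features(chain_sentence, e1, e0, [EC(7)])
        prime = edge_features(chain_sentence, e1, e0, [EC("7p")])
        assert base - prime == Counter()
        assert all(k.startswith("class7:posbow=") for k in prime - base)

    def test_genia_class_flags_given_entities_on_path(self, chain_sentence):
        e1 = chain_sentence.entity_by_id("e1")
        e0 = chain_sentence.entity_by_id("e0")
        feats = edge_features(chain_sentence, e1, e0, [EC(8)])
        assert feats["class8:given_on_path=Protein"] == 1
        assert feats["class8:e2_given=True"] == 1

    def test_unknown_class_rejected(self, chain_sentence):
        e1 = chain_sentence.entity_by_id("e1")
        with pytest.raises(ConfigurationError):
            edge_features(chain_sentence, e1, e1, [FeatureClassId("edge", 9)])


class TestInvariants:
    def test_determinism(self, chain_sentence):
        classes = [TC(i) for i in (1, 2, 3, 4, 5, 6)]
        a = trigger_features(chain_sentence, 1, classes)
        b = trigger_features(chain_sentence, 1, classes)
        assert a == b

    def test_monotone_union(self, chain_sentence):
        classes = [TC(i) for i in (1, 2, 4)]
        union = trigger_features(chain_sentence, 0, classes)
        parts = sum(
            (trigger_features(chain_sentence, 0, [c]) for c in classes), Counter()
        )
        assert union == parts

    def test_locality_outside_neighbourhood(self):
        # chain 0-1-...-7; token 7 is beyond window 3 and walk depth 3 of 0
        words = ["t%d" % i for i in range(8)]
        edges = [(i, i + 1, "dep") for i in range(7)]
        before = make_sentence(words, edges=edges)
        after_words = words[:7] + ["CHANGED"]
        after = make_sentence(after_words, edges=edges)
        for cid in (2, 3, 4, 5, 6):
            assert trigger_features(before, 0, [TC(cid)]) == trigger_features(
                after, 0, [TC(cid)]
            ), f"class {cid} not local"
        # the sentence class, by contrast, must see the edit
        assert trigger_features(before, 0, [TC(1)]) != trigger_features(
            after, 0, [TC(1)]
        )

    def test_feature_size_counts_distinct_types(self):
        ms = [Counter({"a": 2, "b": 1}), Counter({"b": 5, "c": 1})]
        assert feature_size(ms) == 3
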