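"""Negative sampling, common-motif partitioning, balanced mixed training."""
import numpy as np
import pytest

from mhc2lig.alphabet import RESIDUES
from mhc2lig.data import (
    build_training_set,
    common_motif_partition,
    ic50_to_target,
    sample_negatives,
)
from mhc2lig.encoding import EncoderConfig, PeptideInstance, encode_dataset
from mhc2lig.network import NetworkConfig
from mhc2lig.training import (
    TrainRunConfig,
    cross_validate,
    draw_iteration,
    train_network,
)


def pep(seq, **kw):
    kw.setdefault("data_type", "EL")
    return PeptideInstance(seq, **kw)


def random_proteome(rng, n=30, length=200):
    return {f"p{i}": "".join(rng.choice(list(RESIDUES), size=length))
            for i in range(n)}


class TestSampleNegatives:
    def test_counts_follow_five_times_max_length_rule(self, rng):
        proteome = random_proteome(rng)
        positives = [pep("A" * 14, target=1.0) for _ in range(10)] + \
                    [pep("C" * 15, target=1.0) for _ in range(6)]
        negs = sample_negatives(positives, proteome, rng=0)
        per_len = {}
        for n in negs:
            per_len[len(n.sequence)] = per_len.get(len(n.sequence), 0) + 1
        assert per_len == {L: 50 for L in range(11, 20)}
        assert len(negs) == 450

    def test_single_length_rule_collapses(self, rng):
        proteome = random_proteome(rng)
        positives = [pep("W" * 13, target=1.0) for _ in range(4)]
        negs = sample_negatives(positives, proteome, rng=0)
        assert sum(len(n.sequence) == 12 for n in negs) == 20

    def test_reproducible_under_fixed_seed(self, rng):
        proteome = random_proteome(rng)
        positives = [pep("A" * 14, target=1.0)]
        a = sample_negatives(positives, proteome, rng=3)
        b = sample_negatives(positives, proteome, rng=3)
        assert [n.sequence for n in a] == [n.sequence for n in b]

    def test_negatives_carry_true_proteome_context(self, rng):
        proteome = random_proteome(rng, n=3)
        positives = [pep("A" * 14, target=1.0)]
        for n in sample_negatives(positives, proteome, rng=1):
            seq = proteome[n.source_protein_id]
            pos = seq.find(n.sequence)
            assert pos >= 0
            up = n.context_up.lstrip("X")
            assert seq[max(0, pos - len(up)) : pos].endswith(up)
            assert n.target == 0.0 and n.data_type == "EL"

    def test_short_proteome_rejected(self):
        with pytest.raises(ValueError, match="long enough"):
            sample_negatives([pep("A" * 14, target=1.0)], {"p": "ACDEF"}, rng=0)


class TestCommonMotifPartition:
    def test_shared_9mer_forces_same_partition(self):
        shared = "WYFDKACDH"
        instances = [pep("AA" + shared + "KK"), pep(shared + "GGGG")] + \
                    [pep("".join(np.random.default_rng(i).choice(list("GHKNQ"), size=12)))
                     for i in range(10)]
        labels = common_motif_partition(instances, 5)
        assert labels[0] == labels[1]

    def test_transitive_linkage_co_partitions_all_three(self):
        a = "WYFDKACDH"  # A~B via this 9mer
        b = "QQQQQQQQQ"  # B~C via this one
        instances = [pep(a + "KK"), pep(a + b), pep("GG" + b)] + \
                    [pep("".join(np.random.default_rng(i).choice(list("HKNDE"), size=11)))
                     for i in range(8)]
        labels = common_motif_partition(instances, 5)
        assert labels[0] == labels[1] == labels[2]

    def test_distinct_9mer_sets_balance_evenly(self, rng):
        # 10 peptides built from disjoint residue pairs: no shared 9mers
        pairs = ["AC", "DE", "FG", "HI", "KL", "MN", "PQ", "RS", "TV", "WY"]
        instances = [pep((p * 7)[:13]) for p in pairs]
        labels = common_motif_partition(instances, 5)
        assert sorted(np.bincount(labels, minlength=5)) == [2, 2, 2, 2, 2]

    def test_no_9mer_crosses_partitions(self, rng):
        def rand_pep(i):
            r = np.random.default_rng(i)
            return "".join(r.choice(list(RESIDUES), size=int(r.integers(11, 20))))

        instances = [pep(rand_pep(i)) for i in range(300)]
        labels = common_motif_partition(instances, 5)
        seen = {}
        for p, lab in zip(instances, labels):
            s = p.sequence
            for i in range(len(s) - 8):
                mer = s[i : i + 9]
                assert seen.setdefault(mer, lab) == lab

    def test_fewer_instances_than_partitions_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            common_motif_partition([pep("A" * 11)], 5)


class TestBalancedMixing:
    def test_expected_half_of_draws_come_from_each_type(self):
        rng = np.random.default_rng(0)
        el = np.arange(900)
        ba = np.arange(900, 1000)
        n = 4000
        draws = draw_iteration(rng, el, ba, n)
        n_ba = (draws >= 900).sum()
        # binomial(n, 1/2): stay within 4 sigma
        assert abs(n_ba - n / 2) < 4 * np.sqrt(n * 0.25)

    def test_single_type_reduces_to_plain_sampling(self):
        rng = np.random.default_rng(0)
        draws = draw_iteration(rng, np.arange(50), np.array([], dtype=int), 200)
        assert draws.min() >= 0 and draws.max() < 50

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            draw_iteration(np.random.default_rng(0), np.array([], dtype=int),
                           np.array([], dtype=int), 10)


class TestTrainNetwork:
    @pytest.fixture(scope="class")
    def tiny_dataset(self):
        rng = np.random.default_rng(5)
        instances = []
        for i in range(40):
            seq = "".join(rng.choice(list(RESIDUES), size=int(rng.integers(11, 20))))
            instances.append(pep(seq, target=float(i % 2)))
        for i in range(10):
            seq = "".join(rng.choice(list(RESIDUES), size=15))
            instances.append(PeptideInstance(seq, target=0.5, data_type="BA"))
        return encode_dataset(instances, EncoderConfig())

    def test_identical_seed_gives_bit_identical_weights(self, tiny_dataset):
        cfg = NetworkConfig(hidden_units=3, seed=4, iterations=3)
        a = train_network(tiny_dataset, cfg)
        b = train_network(tiny_dataset, cfg)
        np.testing.assert_array_equal(a.w_in, b.w_in)
        np.testing.assert_array_equal(a.w_out_el, b.w_out_el)
        assert a.b_out_el == b.b_out_el

    def test_el_only_training_never_touches_ba_head(self):
        rng = np.random.default_rng(6)
        instances = [pep("".join(rng.choice(list(RESIDUES), size=13)),
                         target=float(i % 2)) for i in range(30)]
        ds = encode_dataset(instances, EncoderConfig())
        cfg = NetworkConfig(hidden_units=3, seed=4, iterations=3)
        from mhc2lig.network import NetworkModel

        init = NetworkModel(cfg, ds.config)
        trained = train_network(ds, cfg)
        np.testing.assert_allclose(trained.w_out_ba, init.w_out_ba, atol=1e-6)


class TestCrossValidate:
    @pytest.fixture(scope="class")
    def cv_setup(self):
        rng = np.random.default_rng(7)
        instances = []
        for i in range(60):
            seq = "".join(rng.choice(list(RESIDUES), size=int(rng.integers(11, 20))))
            instances.append(pep(seq, target=float(i % 2)))
        run_cfg = TrainRunConfig(seeds=(0, 1), hidden_sizes=(2, 3),
                                 n_partitions=5, iterations=2)
        result = cross_validate(instances, run_cfg)
        return instances, run_cfg, result

    def test_every_instance_predicted_exactly_once_out_of_fold(self, cv_setup):
        _, _, result = cv_setup
        assert not np.isnan(result.oof_el).any()
        assert not np.isnan(result.oof_ba).any()

    def test_ensemble_has_seeds_by_hidden_by_folds_members(self, cv_setup):
        _, run_cfg, result = cv_setup
        assert len(result.models) == run_cfg.ensemble_size == 20

    def test_default_run_config_yields_250_networks(self):
        assert TrainRunConfig().ensemble_size == 250

    def test_fold_models_never_see_held_out_instances(self, cv_setup):
        """Retraining a fold without its held-out data reproduces the fold
        model bit-exactly: the held-out instances cannot have influenced it."""
        instances, run_cfg, result = cv_setup
        fold0_net = result.fold_models(0)[0]
        train_instances = [p for p, lab in zip(instances, result.partition_labels)
                          if lab != 0]
        ds = encode_dataset(train_instances, EncoderConfig())
        retrained = train_network(ds, run_cfg.network_config(0, 2))
        np.testing.assert_array_equal(retrained.w_in, fold0_net.w_in)

    def test_empty_partition_rejected(self):
        instances = [pep("ACDEFGHIKLMNP", target=1.0, partition=0)
                     for _ in range(10)]
        with pytest.raises(ValueError, match="empty"):
            cross_validate(instances, TrainRunConfig(seeds=(0,), hidden_sizes=(2,),
                                                     iterations=2))


class TestCombinedVersusSingle:
    def test_adding_ba_data_does_not_hurt_el_ppv(self):
        """Joint training on affinity + elution data keeps the eluted-ligand
        positive predictive value within noise of an elution-only model when
        the two assays share one binding motif."""
        from mhc2lig.metrics import ppv
        from mhc2lig.simulate import WorldConfig, emit_ba, emit_ligands, make_world

        deficits = []
        for seed in range(5):
            world = make_world(WorldConfig(n_ligands=400, n_ba=300, seed=seed,
                                           n_proteins=4000))
            ligands, proteome, _ = emit_ligands(world)
            ba = emit_ba(world)
            # two seeds per fold: a lone badly converged network is exactly
            # what the method's ensembling is there to absorb
            run_cfg = TrainRunConfig(seeds=(seed, seed + 50), hidden_sizes=(10,),
                                     n_partitions=5, iterations=30)
            scores = {}
            for label, extra in (("combined", ba), ("el_only", None)):
                ts = build_training_set(ligands, proteome, ba=extra, rng=seed)
                res = cross_validate(ts.instances, run_cfg)
                is_el = np.array([p.data_type == "EL" for p in ts.instances])
                y = np.array([p.target for p in ts.instances])[is_el]
                scores[label] = ppv(y, res.oof_el[is_el])
            deficits.append(scores["combined"] - scores["el_only"])
        assert all(d >= -0.02 for d in deficits)


class TestBATransform:
    def test_ic50_anchor_points(self):
        assert ic50_to_target(1.0) == pytest.approx(1.0)
        assert ic50_to_target(50000.0) == pytest.approx(0.0)
        assert ic50_to_target(500.0) == pytest.approx(1 - np.log(500) / np.log(50000))

    def test_clamped_to_unit_interval(self):
        assert ic50_to_target(1e7) == 0.0


class TestBuildTrainingSet:
    def test_out_of_range_ligand_rejected(self, rng):
        proteome = random_proteome(rng)
        with pytest.raises(ValueError, match="11-19"):
            build_training_set([pep("A" * 25, target=1.0)], proteome)

    def test_partitions_cover_all_instances(self, rng):
        proteome = random_proteome(rng)
        ligands = [pep("".join(rng.choice(list(RESIDUES), size=14)), target=1.0)
                   for _ in range(12)]
        ts = build_training_set(ligands, proteome, rng=0)
        assert ts.partition_labels is not None
        assert len(ts.partition_labels) == len(ts.instances)
        assert all(p.partition is not None for p in ts.instances)
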