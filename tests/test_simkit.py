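"""Generator behaviour: determinism, planted structure, distributional checks."""

import numpy as np
import pytest
from scipy import stats

from tdmdscreen import simkit
from tdmdscreen.isoforms import ISOFORM_CLASSES
from tdmdscreen.simkit import SimConfig, _nb_draw


def fasta_text(dictionary):
    return "\n".join(f">{e.name}\n{e.sequence}" for e in dictionary.entries)


class TestDictionary:
    def test_seed_determinism_byte_identical(self):
        cfg = SimConfig(seed=1)
        assert fasta_text(simkit.make_mirna_dictionary(cfg)) == fasta_text(
            simkit.make_mirna_dictionary(cfg)
        )

    def test_family_members_share_seed_region(self, small_data):
        fam = [e for e in small_data["dictionary"].guides() if e.family == "fam-1"]
        assert len(fam) == 3
        seeds = {e.sequence[1:8] for e in fam}
        assert len(seeds) == 1
        # members diverge outside the seed region
        assert len({e.sequence for e in fam}) == 3

    def test_planted_identical_guides_merged(self):
        cfg = SimConfig(seed=3, n_families=4, family_sizes=(1,) * 4,
                        plant_identical_guides=2)
        d = simkit.make_mirna_dictionary(cfg)
        # all-pairs string-equality oracle: no two entries share a sequence
        seqs = [e.sequence for e in d.entries]
        for i in range(len(seqs)):
            for j in range(i + 1, len(seqs)):
                assert seqs[i] != seqs[j]
        merged = d.merge_map["mir-1.1"]
        assert set(merged) == {"mir-1.1", "mir-1.1-copy1", "mir-1.1-copy2"}

    def test_guide_and_passenger_per_locus(self, small_data):
        d = small_data["dictionary"]
        for g in d.guides():
            assert len(d.passengers_of(g.locus)) == 1

    def test_rna_alphabet(self, small_data):
        for e in small_data["dictionary"].entries:
            assert set(e.sequence) <= set("ACGU")

    def test_short_mature_rejected(self):
        with pytest.raises(ValueError, match="19-nt prefix"):
            simkit.make_mirna_dictionary(SimConfig(mature_length=19))

    def test_spike_prefixes_disjoint(self, small_data, small_cfg):
        spikes = small_data["spikes"]
        taken = {e.sequence[:19] for e in small_data["dictionary"].entries}
        assert all(e.sequence[:19] not in taken for e in spikes.entries)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs,msg",
        [
            ({"dispersion": -0.1}, "dispersion"),
            ({"isoform_fracs": {"FL": 0.5}}, "sum to 1"),
            ({"sensitive_fold_range": (0.8, 2.0)}, "exceed 1"),
            ({"pirna_blocks": ((0, 5, -1.0), (3, 5, -1.0))}, "overlapping"),
        ],
    )
    def test_invalid_config_rejected(self, kwargs, msg):
        with pytest.raises(ValueError, match=msg):
            SimConfig(**kwargs).validate()


class TestTruth:
    def test_invariants_hold(self, small_data):
        truth = small_data["truth"]
        truth.validate()
        for stage in truth.sensitive.columns:
            for g in truth.sensitive_guides(stage):
                assert truth.fold.loc[g, stage] > 1.0
        passengers = [n for n in truth.fold.index if n.endswith("*")]
        assert ((truth.fold.loc[passengers] >= 0.8).all().all()
                and (truth.fold.loc[passengers] <= 1.25).all().all())


class TestCounts:
    def test_seed_determinism(self, small_cfg, small_data):
        again = simkit.simulate_counts(
            small_data["dictionary"], small_data["truth"], small_cfg
        )
        assert again.counts.equals(small_data["counts"].counts)

    def test_null_fold_gives_unit_mean_ratio(self):
        """With no planted effects the mutant/WT mean count ratio is ~1."""
        ratios = []
        for seed in range(10):
            cfg = SimConfig(seed=seed, n_families=50, family_sizes=(1,) * 50,
                            frac_sensitive=0.0, depth=1e6, depth_sd=0.0,
                            dispersion=0.0)
            d = simkit.make_mirna_dictionary(cfg)
            truth = simkit.make_truth(d, cfg)
            guides = [e.name for e in d.guides()]
            counts = simkit.simulate_counts(d, truth, cfg)
            wt = counts.counts[counts.libraries(genotype="WT")].sum(axis=1)
            mut = counts.counts[counts.libraries(genotype="mutant")].sum(axis=1)
            ratios.append((mut[guides].sum()) / wt[guides].sum())
        # Poisson totals ~ 1e6 per library: 3 SE on the ratio is ~3*sqrt(2/2e6)
        se = np.sqrt(2.0 / 2e6)
        assert abs(np.mean(ratios) - 1.0) < 3 * se / np.sqrt(len(ratios)) + 3 * se

    def test_poisson_limit_variance_equals_mean(self):
        rng = np.random.default_rng(0)
        draws = _nb_draw(rng, np.full(10_000, 50.0), alpha=0.0)
        assert draws.var() == pytest.approx(draws.mean(), rel=0.1)

    def test_nb_variance_inflation(self):
        rng = np.random.default_rng(1)
        mu, alpha = 200.0, 0.2
        draws = _nb_draw(rng, np.full(20_000, mu), alpha)
        expected_var = mu + alpha * mu**2
        assert draws.var() == pytest.approx(expected_var, rel=0.15)

    def test_counts_are_nonneg_integers(self, small_data):
        arr = small_data["counts"].counts.to_numpy()
        assert (arr >= 0).all() and np.issubdtype(arr.dtype, np.integer)


class TestEmitReads:
    def test_degenerate_vector_emits_only_full_length(self, small_cfg, small_data):
        fracs = {c: 0.0 for c in ISOFORM_CLASSES}
        fracs["FL"] = 1.0
        cfg = small_cfg.with_(isoform_fracs=fracs)
        reads = simkit.emit_reads(
            small_data["counts"], small_data["truth"], small_data["dictionary"], cfg
        )
        matures = {s.replace("U", "T")
                   for s in small_data["dictionary"].sequences.values()}
        lib = next(iter(reads))
        assert {r.sequence for r in reads[lib]} <= matures

    def test_reads_carry_q40(self, small_cfg, small_data):
        reads = simkit.emit_reads(
            small_data["counts"], small_data["truth"], small_data["dictionary"],
            small_cfg,
        )
        lib = next(iter(reads))
        assert all(q >= 30 for q in reads[lib][0].quality)

    def test_spike_monoa_miscall_recovered(self):
        """Planted mono-A miscall rate is recovered within 3 binomial SE."""
        rate = 0.001
        cfg = SimConfig(seed=5, n_families=2, family_sizes=(1, 1), depth=4e5,
                        spike_proportion=0.5,
                        spike_miscalls={"+A": rate})
        data = simkit.simulate_dataset(cfg)
        reads = simkit.emit_reads(
            data["counts"], data["truth"], data["dictionary"], cfg, data["spikes"]
        )
        lib = next(iter(reads))
        spike_fl = {e.sequence.replace("U", "T") for e in data["spikes"].entries}
        spike_a = {e.sequence.replace("U", "T") + "A" for e in data["spikes"].entries}
        n_fl = sum(r.sequence in spike_fl for r in reads[lib])
        n_a = sum(r.sequence in spike_a for r in reads[lib])
        n = n_fl + n_a
        se = np.sqrt(rate * (1 - rate) / n)
        assert abs(n_a / n - rate) < 3 * se


class TestPirna:
    def test_block_log2fc_recovered(self):
        """Planted -2 block: observed mean log2FC across the block < -1.5."""
        cfg = SimConfig(seed=9, pirna_mean_log_mu=6.0, dispersion=0.01)
        truth = simkit.make_truth(simkit.make_mirna_dictionary(cfg), cfg)
        counts, records = simkit.simulate_pirna_counts(cfg, truth)
        blk = truth.pirna_blocks[0]
        names = [f"21ur-{i + 1}" for i in range(blk["start_idx"],
                                                blk["start_idx"] + blk["size"])]
        wt = counts.counts[counts.libraries(genotype="WT")].mean(axis=1)
        mut = counts.counts[counts.libraries(genotype="mutant")].mean(axis=1)
        obs = np.log2(mut[names] / wt[names])
        assert obs.mean() < -1.5

    def test_zero_block_fc_is_structureless(self):
        cfg = SimConfig(seed=9, pirna_blocks=((20, 8, 0.0),))
        truth = simkit.make_truth(simkit.make_mirna_dictionary(cfg), cfg)
        counts, _ = simkit.simulate_pirna_counts(cfg, truth)
        wt = counts.counts[counts.libraries(genotype="WT")].mean(axis=1)
        mut = counts.counts[counts.libraries(genotype="mutant")].mean(axis=1)
        ratio = mut.sum() / wt.sum()
        assert 0.8 < ratio < 1.25

    def test_bed_roundtrip(self, tmp_path):
        from tdmdscreen import pirnaregion

        cfg = SimConfig(seed=2)
        truth = simkit.make_truth(simkit.make_mirna_dictionary(cfg), cfg)
        _, records = simkit.simulate_pirna_counts(cfg, truth)
        path = tmp_path / "pirnas.bed"
        pirnaregion.write_bed(records, path)
        back = pirnaregion.read_bed(path)
        assert list(back["start"]) == list(records["start"])
        assert list(back["end"]) == list(records["end"])
        assert list(back["name"]) == list(records["name"])


class TestMrnaTable:
    def test_planted_repression_detectable(self):
        cfg = SimConfig(seed=4, mrna_target_effect=-0.5, mrna_conserved_effect=-0.5)
        truth = simkit.make_truth(simkit.make_mirna_dictionary(cfg), cfg)
        table = simkit.simulate_mrna_table(truth, cfg)
        t = table[table.predicted_target]["log2fc"]
        nt = table[~table.predicted_target]["log2fc"]
        assert stats.ks_2samp(t, nt).pvalue < 0.01
        assert t.mean() < nt.mean()

    def test_no_effect_is_null(self):
        """Zero planted effect: K-S p > 0.05 in at least 9 of 10 seeds."""
        hits = 0
        for seed in range(10):
            cfg = SimConfig(seed=seed, mrna_target_effect=0.0,
                            mrna_conserved_effect=0.0)
            truth = simkit.make_truth(simkit.make_mirna_dictionary(cfg), cfg)
            table = simkit.simulate_mrna_table(truth, cfg)
            t = table[table.predicted_target]["log2fc"]
            nt = table[~table.predicted_target]["log2fc"]
            hits += stats.ks_2samp(t, nt).pvalue > 0.05
        assert hits >= 9

    def test_positive_effect_rejected(self):
        cfg = SimConfig(mrna_target_effect=0.1)
        truth = simkit.make_truth(simkit.make_mirna_dictionary(SimConfig()), SimConfig())
        with pytest.raises(ValueError, match="repression"):
            simkit.simulate_mrna_table(truth, cfg)

    def test_conserved_implies_predicted(self):
        cfg = SimConfig(seed=6)
        truth = simkit.make_truth(simkit.make_mirna_dictionary(cfg), cfg)
        table = simkit.simulate_mrna_table(truth, cfg)
        assert (table.loc[table.conserved_target, "predicted_target"]).all()
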