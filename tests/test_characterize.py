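"""Posterior classification, Phred conversion, and count/depth profiling."""

import numpy as np
import pytest

from kmerstat.cascade import CascadeConfig, count_reads
from kmerstat.characterize import (
    PosteriorUndefinedError,
    classify,
    classify_counts,
    count_depth_profile,
    error_prob_to_phred,
    kmer_min_phred,
    phred_to_error_prob,
    posterior,
)
from kmerstat.mixture import ComponentSpec, MixtureModel


@pytest.fixture
def model():
    """Typical fitted shape: dominant error at low counts, peaks at 8/16."""
    return MixtureModel(
        [
            ComponentSpec("exponential", {"rate": 1.5}, 0.8),
            ComponentSpec("poisson", {"mean": 8.0}, 0.05),
            ComponentSpec("poisson", {"mean": 16.0}, 0.15),
        ],
        40,
    )


class TestPosterior:
    def test_sums_to_one_everywhere(self, model):
        for x in range(1, 41):
            assert posterior(model, x).sum() == pytest.approx(1.0)

    def test_hand_computed_at_x5(self, model):
        post = posterior(model, 5)
        pmfs = model.component_pmfs()[:, 4]
        num = model.weights * pmfs
        assert np.allclose(post, num / num.sum())

    def test_zero_component_density_gives_zero_posterior(self):
        model = MixtureModel(
            [
                ComponentSpec("exponential", {"rate": 30.0}, 0.5),  # no mass beyond x~2
                ComponentSpec("poisson", {"mean": 10.0}, 0.5),
            ],
            30,
        )
        assert posterior(model, 20)[0] == pytest.approx(0.0, abs=1e-12)

    def test_out_of_support_rejected(self, model):
        with pytest.raises(ValueError):
            posterior(model, 0)

    def test_undefined_posterior_raises(self):
        # all components concentrated far below x -> F(x) underflows to 0
        model = MixtureModel(
            [
                ComponentSpec("exponential", {"rate": 20.0}, 0.5),
                ComponentSpec("normal", {"mean": 2.0, "sd": 0.31}, 0.5),
            ],
            600,
        )
        with pytest.raises(PosteriorUndefinedError):
            posterior(model, 600)

    def test_error_posterior_monotone_beyond_mode(self, model):
        p_err = [posterior(model, x)[0] for x in range(2, 41)]
        assert all(a >= b - 1e-12 for a, b in zip(p_err, p_err[1:]))


class TestClassify:
    def test_low_counts_are_error(self, model):
        assert classify(model, 1) == "error"

    def test_peak_counts_labelled_by_component(self, model):
        assert classify(model, 8) == "heterozygous"
        assert classify(model, 16) == "homozygous"
        assert classify(model, 30) == "homozygous"

    def test_tie_breaks_toward_lower_mean(self):
        # two identical genomic components: posterior ties exactly
        model = MixtureModel(
            [
                ComponentSpec("exponential", {"rate": 2.0}, 0.2),
                ComponentSpec("poisson", {"mean": 10.0}, 0.4),
                ComponentSpec("poisson", {"mean": 10.0}, 0.4),
            ],
            30,
        )
        assert classify(model, 10) == "heterozygous"

    def test_vectorized_agrees_with_scalar(self, model):
        counts = np.arange(1, 41)
        labels = ("error", "heterozygous", "homozygous")
        codes = classify_counts(model, counts)
        assert [labels[c] for c in codes] == [classify(model, int(x)) for x in counts]

    def test_deterministic(self, model):
        assert classify(model, 12) == classify(model, 12)

    def test_fixture_confusion_structure(self, tiny_fixture):
        """Error k-mers are separated near-perfectly; hom beats het accuracy."""
        from kmerstat.histogram import histogram_from_counts
        from kmerstat.mixture import DEConfig, fit
        from kmerstat.simulate import label_kmers

        genome, reads = tiny_fixture
        seqs = [r.sequence for r in reads]
        truth = label_kmers(seqs, genome, 21)
        hist = histogram_from_counts(np.minimum(truth.counts, 255))
        result = fit(hist, de=DEConfig(seed=9))
        codes = classify_counts(result.model, np.minimum(truth.counts, hist.c))
        acc = {}
        for lab in (0, 1, 2):
            m = truth.label == lab
            acc[lab] = (codes[m] == lab).mean()
        assert acc[0] > 0.95  # error k-mers nearly perfectly identified
        assert acc[2] > acc[1]  # homozygous easier than heterozygous
        assert acc[2] > 0.9


class TestPhred:
    def test_p_point_one_is_q10(self):
        assert error_prob_to_phred(0.1) == pytest.approx(10.0)

    def test_p_one_is_q0(self):
        assert error_prob_to_phred(1.0) == pytest.approx(0.0)

    def test_round_trip(self):
        for p in (1.0, 0.5, 0.1, 1e-4):
            assert phred_to_error_prob(error_prob_to_phred(p)) == pytest.approx(p, abs=1e-12)

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            error_prob_to_phred(0.0)

    def test_min_phred_windows(self):
        q = np.array([30, 40, 10, 40, 40])
        assert kmer_min_phred(q, 3).tolist() == [10, 10, 10]
        assert kmer_min_phred("IIII", 2).tolist() == [40, 40, 40]


class TestCountDepthProfile:
    @pytest.fixture
    def store(self):
        kmer = "ACGTTGCAGGTCAAT"
        reads = [
            "GG" + kmer, "CC" + kmer, "TT" + kmer, "AA" + kmer, "CA" + kmer,  # 5 reads, once
            kmer + "GGCC" + kmer, kmer + "TTAA" + kmer,  # repeats within reads
        ]
        config = CascadeConfig(k=15, depth=True, error_rate=1e-6)
        return count_reads(reads, config, distinct_counts={"global": 512, "output": 512}), reads

    def test_ratio_one_for_once_per_read(self, store):
        st, reads = store
        profile = count_depth_profile(st, reads)
        row = profile.table[profile.table.kmer == min("ACGTTGCAGGTCAAT", "ATTGACCTGCAACGT")]
        assert row["count"].item() == 9  # 5 + 2*2
        assert row["depth"].item() == 7
        assert row["ratio"].item() == pytest.approx(9 / 7)

    def test_triple_occurrence_ratio(self):
        kmer = "ACGTTGCAGGTCAAT"
        read = kmer + "GG" + kmer + "TT" + kmer  # 3x in one read
        config = CascadeConfig(k=15, depth=True, error_rate=1e-6)
        st = count_reads([read, read], config, distinct_counts={"global": 512, "output": 512})
        profile = count_depth_profile(st, [read, read])
        row = profile.table.loc[profile.table["count"].idxmax()]
        assert row["count"] == 6 and row["depth"] == 2 and row["ratio"] == pytest.approx(3.0)

    def test_density_totals(self, store):
        st, reads = store
        profile = count_depth_profile(st, reads)
        assert profile.density.sum() == len(profile.table)

    def test_depth_missing_is_error(self, small_reads):
        config = CascadeConfig(k=15)
        st = count_reads(small_reads[:5], config, distinct_counts={"output": 1024})
        with pytest.raises(ValueError, match="depth"):
            count_depth_profile(st, small_reads[:5])

    def test_tandem_repeat_ratio_tracks_proximity(self, np_rng):
        """Higher count/depth ratio <-> shorter spacing between occurrences."""
        # genome with a tandem block (close repeats) and a dispersed repeat
        unit = "ACGTTGCAGGTCAATCCGGATAGCT"
        spacer = "".join(np_rng.choice(list("ACGT"), size=400))
        genome = unit * 6 + spacer + (unit[::-1] + spacer) * 3
        reads = [genome[i : i + 120] for i in range(0, len(genome) - 120, 17)]
        config = CascadeConfig(k=15, depth=True, error_rate=1e-6)
        st = count_reads(reads, config, distinct_counts={"global": 40000, "output": 40000})
        profile = count_depth_profile(st, reads)
        t = profile.table
        tandem = t[t.kmer.isin({min(unit[i:i+15], _rc(unit[i:i+15])) for i in range(6)})]
        assert (tandem["ratio"] > 1.2).all()


def _rc(s):
    return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]
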