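"""Similarity metrics against direct-formula oracles; accuracy metrics."""

import numpy as np
import pytest

from gifms.backend import MockBackend, MockOracleConfig
from gifms.chem import compute_mz, parse_molecule
from gifms.evaluation import (
    BinnedSpectrum,
    bin_spectrum,
    chemical_validity,
    cosine_similarity,
    evaluate_run,
    fragment_accuracy,
    jensen_shannon_similarity,
    precursor_baseline,
    subformula_accuracy,
    substructure_validity,
)
from gifms.fragmenter import FragmentRecord, enumerate_fragments
from gifms.pipeline import GifRunConfig, simulate_spectrum


def _binned(vector, bin_width=1.0):
    vector = np.asarray(vector, dtype=float)
    return BinnedSpectrum(vector=vector, bin_width=bin_width, max_mz=bin_width * len(vector))


def oracle_cosine(a, b):
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(np.dot(a, b) / (na * nb))


def oracle_js_similarity(a, b):
    """Direct-formula Jensen-Shannon similarity with base-2 logs."""
    p, q = np.asarray(a, float), np.asarray(b, float)
    p, q = p / p.sum(), q / q.sum()
    m = 0.5 * (p + q)

    def kl(x, y):
        mask = x > 0
        return float(np.sum(x[mask] * np.log2(x[mask] / y[mask])))

    return 1.0 - (0.5 * kl(p, m) + 0.5 * kl(q, m))


class TestBinning:
    def test_single_peak_single_bin(self):
        binned = bin_spectrum([(10.5, 1.0)], bin_width=1.0, max_mz=20.0)
        assert binned.vector[10] == 1.0
        assert np.count_nonzero(binned.vector) == 1

    def test_peaks_in_one_bin_summed(self):
        binned = bin_spectrum([(10.1, 0.4), (10.9, 0.6)], bin_width=1.0, max_mz=20.0)
        assert binned.vector[10] == pytest.approx(1.0)

    def test_peak_at_max_mz_dropped(self):
        binned = bin_spectrum([(20.0, 1.0), (5.0, 1.0)], bin_width=1.0, max_mz=20.0)
        assert binned.n_dropped == 1
        assert binned.vector.sum() == pytest.approx(1.0)

    def test_total_intensity_conserved_below_max(self):
        peaks = [(float(mz), 0.5) for mz in range(1, 100)]
        binned = bin_spectrum(peaks, bin_width=0.01, max_mz=1005.0)
        assert binned.vector.sum() == pytest.approx(sum(i for _, i in peaks))


class TestSimilarities:
    def test_identical_spectra_unit_scores(self):
        a = _binned([1.0, 2.0, 0.0, 3.0])
        assert cosine_similarity(a, a) == pytest.approx(1.0)
        assert jensen_shannon_similarity(a, a) == pytest.approx(1.0)

    def test_disjoint_spectra_zero_scores(self):
        a, b = _binned([1.0, 0.0]), _binned([0.0, 1.0])
        assert cosine_similarity(a, b) == 0.0
        assert jensen_shannon_similarity(a, b) == pytest.approx(0.0, abs=1e-12)

    def test_hand_derived_values(self):
        a, b = _binned([1.0, 0.0]), _binned([1.0, 1.0])
        assert cosine_similarity(a, b) == pytest.approx(0.7071, abs=1e-4)
        c = _binned([0.5, 0.5])
        assert jensen_shannon_similarity(a, c) == pytest.approx(0.6887, abs=1e-3)

    def test_empty_vector_handling(self):
        zero, nonzero = _binned([0.0, 0.0]), _binned([1.0, 0.0])
        assert cosine_similarity(zero, nonzero) == 0.0
        assert jensen_shannon_similarity(zero, nonzero) == 0.0
        with pytest.raises(ValueError):
            jensen_shannon_similarity(zero, zero)

    def test_bin_parameter_mismatch_rejected(self):
        a = _binned([1.0, 0.0], bin_width=1.0)
        b = _binned([1.0, 0.0], bin_width=0.5)
        with pytest.raises(ValueError):
            cosine_similarity(a, b)

    def test_agreement_with_oracles_on_random_vectors(self):
        rng = np.random.default_rng(17)
        for _ in range(200):
            a = rng.random(32) * (rng.random(32) < 0.5)
            b = rng.random(32) * (rng.random(32) < 0.5)
            if a.sum() == 0 or b.sum() == 0:
                continue
            sa, sb = _binned(a), _binned(b)
            assert cosine_similarity(sa, sb) == pytest.approx(oracle_cosine(a, b), abs=1e-10)
            assert jensen_shannon_similarity(sa, sb) == pytest.approx(
                oracle_js_similarity(a, b), abs=1e-10
            )
            # symmetry and bounds
            assert cosine_similarity(sa, sb) == pytest.approx(cosine_similarity(sb, sa))
            assert 0.0 <= jensen_shannon_similarity(sa, sb) <= 1.0


class TestAccuracies:
    def test_perfect_and_empty_generation(self, toluene):
        reference = enumerate_fragments(toluene, 1)
        generated = list(reference)
        assert fragment_accuracy(generated, reference) == 100.0
        assert subformula_accuracy(generated, reference) == 100.0
        assert fragment_accuracy([], reference) == 0.0
        assert subformula_accuracy([], reference) == 0.0

    def test_partial_overlap_counts(self, ethanol):
        reference = enumerate_fragments(ethanol, 1)  # 5 members
        generated = list(reference)[:2]
        assert fragment_accuracy(generated, reference) == pytest.approx(40.0)

    def test_structure_match_implies_formula_match(self, toluene):
        reference = enumerate_fragments(toluene, 2)
        generated = list(reference)[::2]
        assert fragment_accuracy(generated, reference) <= subformula_accuracy(
            generated, reference
        )

    def test_isomer_counts_for_subformula_only(self, settings):
        parent = parse_molecule("CC(C)CC")
        reference = enumerate_fragments(parent, 2)
        isobutane = next(f for f in reference if f.smiles == "CC(C)C")
        nbutane_key = parse_molecule("CCCC").canonical_key
        assert nbutane_key in reference.keys()
        generated = [isobutane]
        # formula C4H10 recovered, but only 1 of the reference structures
        assert subformula_accuracy(generated, reference) > 0
        assert fragment_accuracy(generated, reference) == pytest.approx(
            100.0 / len(reference)
        )

    def test_chemical_validity_fraction(self):
        assert chemical_validity(["CC", "CO", "xx((", "C"]) == pytest.approx(75.0)
        assert chemical_validity(["xx((", "yy))"]) == 0.0
        with pytest.raises(ValueError):
            chemical_validity([])

    def test_substructure_validity_fraction(self, toluene, benzene):
        decoy = parse_molecule("ClCCl")
        fragments = [benzene, parse_molecule("CC"), parse_molecule("C"), decoy]
        assert substructure_validity(fragments, toluene) == pytest.approx(75.0)

    def test_empty_reference_rejected(self, ethanol):
        empty = enumerate_fragments(ethanol, 1)
        empty.members = []
        empty._by_key = {}
        with pytest.raises(ValueError):
            fragment_accuracy([], empty)


class TestPrecursorBaseline:
    def test_glycine_single_peak(self, glycine):
        spectrum = precursor_baseline(glycine, "[M+H]+")
        assert len(spectrum.peaks) == 1
        assert spectrum.peaks[0].mz == pytest.approx(76.03930, abs=1e-4)
        assert spectrum.peaks[0].intensity == 1.0
        assert spectrum.peaks[0].label.canonical_key == glycine.canonical_key

    def test_self_cosine_is_one(self, glycine):
        spectrum = precursor_baseline(glycine, "[M+H]+")
        binned = bin_spectrum(spectrum.peak_array())
        assert cosine_similarity(binned, binned) == pytest.approx(1.0)


class TestEvaluateRun:
    def test_self_consistency_on_oracle_run(self, settings):
        molecules = [parse_molecule(s) for s in ("CCO", "NCC(=O)O", "Cc1ccccc1")]
        backend = MockBackend(MockOracleConfig(fragment_depth=1))
        simulated, references = [], []
        for molecule in molecules:
            spectrum = simulate_spectrum(molecule, settings, backend, GifRunConfig())
            simulated.append(spectrum)
            references.append((spectrum.peak_array(), enumerate_fragments(molecule, 1)))
        report = evaluate_run(simulated, references)
        assert report.fragment_accuracy == 100.0
        assert report.subformula_accuracy == 100.0
        assert report.chemical_validity == 100.0
        assert report.substructure_validity == 100.0
        assert report.cosine_similarity == pytest.approx(1.0)
        assert report.jensen_shannon_similarity == pytest.approx(1.0)
        assert report.n_items == 3

    def test_single_item_equals_its_metrics(self, ethanol, settings):
        backend = MockBackend(MockOracleConfig(fragment_depth=1))
        spectrum = simulate_spectrum(ethanol, settings, backend, GifRunConfig())
        report = evaluate_run([spectrum], [(spectrum.peak_array(), enumerate_fragments(ethanol, 1))])
        assert report.n_items == 1
        assert report.fragment_accuracy == 100.0

    def test_empty_or_misaligned_inputs_rejected(self, ethanol):
        with pytest.raises(ValueError):
            evaluate_run([], [])
        backend = MockBackend(MockOracleConfig(fragment_depth=1))
        from gifms.chem import ExperimentSettings

        spectrum = simulate_spectrum(ethanol, ExperimentSettings(), backend, GifRunConfig())
        with pytest.raises(ValueError):
            evaluate_run([spectrum], [])
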