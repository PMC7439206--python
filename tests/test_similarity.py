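import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dewalk import (
    AssociationData,
    DataError,
    KernelParams,
    SimilarityMatrix,
    SymptomData,
    cosine_similarity,
    gip_kernel,
    integrate_disease_similarity,
    symptom_similarity,
    tfidf_weights,
)


def brute_force_gip(profiles: np.ndarray, gamma_prime: float = 1.0) -> np.ndarray:
    """Independent double-loop oracle for the GIP kernel."""
    n = profiles.shape[0]
    gamma = gamma_prime / np.mean([np.dot(p, p) for p in profiles])
    M = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            d = profiles[i] - profiles[j]
            M[i, j] = np.exp(-gamma * np.dot(d, d))
    return M


def _assoc(A):
    A = np.asarray(A, dtype=float)
    return AssociationData(
        [f"d{i}" for i in range(A.shape[0])],
        [f"m{j}" for j in range(A.shape[1])],
        A,
    )


class TestGipKernel:
    def test_two_disjoint_unit_profiles(self):
        # profiles (1,0) and (0,1): mean squared norm 1, gamma 1, distance^2 = 2
        KD = gip_kernel(_assoc([[1, 0], [0, 1]]), "diseases")
        assert KD.M[0, 1] == pytest.approx(np.exp(-2), abs=1e-12)
        assert KD.M[0, 1] == pytest.approx(0.13534, abs=5e-6)

    def test_identical_profiles_score_one(self):
        KD = gip_kernel(_assoc([[1, 0, 1], [1, 0, 1]]), "diseases")
        assert KD.M[0, 1] == pytest.approx(1.0, abs=1e-15)

    def test_all_zero_profiles_error_not_nan(self):
        with pytest.raises(DataError):
            gip_kernel(_assoc(np.zeros((3, 4))), "diseases")

    @pytest.mark.parametrize("axis", ["diseases", "microbes"])
    def test_matches_brute_force_oracle(self, axis):
        rng = np.random.default_rng(42)
        for _ in range(20):
            A = (rng.random((6, 8)) < 0.4).astype(float)
            if A.sum() == 0:
                continue
            sim = gip_kernel(_assoc(A), axis)
            profiles = A if axis == "diseases" else A.T
            expected = brute_force_gip(profiles)
            np.testing.assert_allclose(sim.M, expected, atol=1e-12)
            np.testing.assert_allclose(sim.M, sim.M.T, atol=1e-12)
            np.testing.assert_allclose(np.diag(sim.M), 1.0, atol=1e-15)
            assert (sim.M >= 0).all() and (sim.M <= 1).all()

    def test_shared_association_never_decreases_similarity(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            A = (rng.random((5, 8)) < 0.35).astype(float)
            if A.sum() == 0:
                continue
            i, j = rng.choice(5, size=2, replace=False)
            col = rng.integers(8)
            before = gip_kernel(_assoc(A), "diseases").M[i, j]
            A2 = A.copy()
            A2[i, col] = A2[j, col] = 1.0
            after = gip_kernel(_assoc(A2), "diseases").M[i, j]
            assert after >= before - 1e-12

    def test_gamma_prime_scales_bandwidth(self):
        A = [[1, 0], [0, 1]]
        narrow = gip_kernel(_assoc(A), "diseases", KernelParams(gamma_prime=2.0))
        assert narrow.M[0, 1] == pytest.approx(np.exp(-4), abs=1e-12)


class TestTfidf:
    def test_ubiquitous_symptom_gets_zero_weight(self):
        sym = SymptomData(["d1", "d2"], ["s1"], np.array([[2.0, 5.0]]))
        np.testing.assert_allclose(tfidf_weights(sym), 0.0, atol=1e-15)

    def test_exclusive_symptom_weight(self):
        # N=2 diseases, count 3 in exactly one disease -> 3*log(2)
        sym = SymptomData(["d1", "d2"], ["s1"], np.array([[3.0, 0.0]]))
        W = tfidf_weights(sym)
        assert W[0, 0] == pytest.approx(3 * np.log(2), abs=1e-12)
        assert W[0, 1] == 0.0

    def test_absent_symptom_row_stays_zero(self):
        sym = SymptomData(["d1", "d2"], ["s1", "s2"], np.array([[0.0, 0.0], [1.0, 0.0]]))
        W = tfidf_weights(sym)
        np.testing.assert_array_equal(W[0], [0.0, 0.0])


class TestCosine:
    def test_disjoint_and_identical_and_half(self):
        # columns: d0=(1,1,0), d1=(0,1,1), d2=(1,0,1)
        W = np.array([[1, 0, 1], [1, 1, 0], [0, 1, 1]], dtype=float)
        sim = cosine_similarity(W, ["d0", "d1", "d2"])
        assert sim.M[0, 1] == pytest.approx(0.5, abs=1e-12)  # (1,1,0)x(0,1,1)
        same = cosine_similarity(np.array([[2.0, 2.0], [1.0, 1.0]]), ["a", "b"])
        assert same.M[0, 1] == pytest.approx(1.0, abs=1e-12)
        disjoint = cosine_similarity(np.array([[1.0, 0.0], [0.0, 3.0]]), ["a", "b"])
        assert disjoint.M[0, 1] == 0.0

    def test_zero_vector_convention(self):
        sim = cosine_similarity(np.array([[1.0, 0.0], [2.0, 0.0]]), ["a", "b"])
        assert sim.M[0, 1] == 0.0 and sim.M[1, 0] == 0.0
        assert sim.M[1, 1] == 1.0  # diagonal stays 1 even for the zero vector

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_log_base_invariance(self, seed):
        rng = np.random.default_rng(seed)
        C = rng.integers(0, 6, size=(7, 5)).astype(float)
        sym = SymptomData([f"d{i}" for i in range(5)], [f"s{k}" for k in range(7)], C)
        S_e = cosine_similarity(tfidf_weights(sym), sym.disease_labels).M
        S_10 = cosine_similarity(tfidf_weights(sym, log_base=10), sym.disease_labels).M
        np.testing.assert_allclose(S_e, S_10, atol=1e-12)


class TestIntegration:
    def _sim(self, M, kind):
        return SimilarityMatrix(["a", "b"], np.asarray(M, dtype=float), kind)

    def test_mean_is_idempotent_on_equal_blocks(self):
        KD = self._sim([[1, 0.3], [0.3, 1]], "KD")
        SD = integrate_disease_similarity(KD, self._sim(KD.M, "SDM"))
        np.testing.assert_allclose(SD.M, KD.M, atol=1e-15)

    def test_elementwise_mean(self):
        KD = self._sim([[1, 0.6], [0.6, 1]], "KD")
        SDM = self._sim([[1, 0.2], [0.2, 1]], "SDM")
        assert integrate_disease_similarity(KD, SDM).M[0, 1] == pytest.approx(0.4)

    def test_absent_symptoms_fall_back_to_kernel(self, caplog):
        KD = self._sim([[1, 0.6], [0.6, 1]], "KD")
        with caplog.at_level("WARNING", logger="dewalk.similarity"):
            SD = integrate_disease_similarity(KD, None)
        np.testing.assert_allclose(SD.M, KD.M)
        assert SD.kind == "SD"
        assert any("fallback" in r.message for r in caplog.records)

    def test_label_mismatch_rejected(self):
        KD = self._sim([[1, 0.6], [0.6, 1]], "KD")
        SDM = SimilarityMatrix(["a", "c"], np.eye(2), "SDM")
        with pytest.raises(DataError):
            integrate_disease_similarity(KD, SDM)


def test_symptom_similarity_end_to_end(toy_symptoms):
    sim = symptom_similarity(toy_symptoms)
    assert sim.kind == "SDM"
    np.testing.assert_allclose(sim.M, sim.M.T, atol=1e-12)
    np.testing.assert_allclose(np.diag(sim.M), 1.0, atol=1e-12)
    assert (sim.M >= 0).all() and (sim.M <= 1).all()
    # the two disease groups of the fixture share symptoms within groups
    assert sim.M[0, 1] > sim.M[0, 2]
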