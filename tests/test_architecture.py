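"""Mutational-architecture construction and sampling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from casteage import (
    SCENARIOS,
    ConfigurationError,
    MutationArchitecture,
    TraitIndexLayout,
    build_partial_correlation,
    nearest_correlation,
    partial_to_covariance,
    sample_mutation,
)
from casteage.architecture import BLOCK_ORDER


# ---------------------------------------------------------------------------
# Independent oracle: enumerate all index pairs and apply the verbal
# coupling rules for each scenario, entry by entry.
# ---------------------------------------------------------------------------

def oracle_partial_correlation(scenario, k, rho, delay):
    layout = TraitIndexLayout(k)
    n = layout.n
    P = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            ci, ti, ai = layout.decode(i)
            cj, tj, aj = layout.decode(j)
            if i == j:
                P[i, j] = 1.0
                continue
            coupled = False
            if scenario == "WCWT":
                # same caste, same trait, ages delay apart; sterile workers
                # exempt the worker-fecundity block
                coupled = (ci == cj and ti == tj
                           and not (ci == "worker" and ti == "fecundity")
                           and abs(ai - aj) == delay)
            elif scenario == "WCBT":
                # queen fecundity at a <-> queen survival at a + delay
                coupled = (ci == cj == "queen" and (
                    (ti == "fecundity" and tj == "survival" and aj - ai == delay)
                    or (ti == "survival" and tj == "fecundity" and ai - aj == delay)))
            elif scenario == "BCWT":
                # queen survival <-> worker survival, same age
                coupled = (ti == tj == "survival" and ci != cj and ai == aj)
            elif scenario == "BCBT":
                # queen fecundity <-> worker survival, same age
                coupled = (ai == aj and (
                    (ci, ti) == ("queen", "fecundity") and (cj, tj) == ("worker", "survival")
                    or (ci, ti) == ("worker", "survival") and (cj, tj) == ("queen", "fecundity")))
            if coupled:
                P[i, j] = rho
    return P


@pytest.mark.parametrize("scenario", SCENARIOS)
@pytest.mark.parametrize("k", [8, 20])
def test_partial_correlation_matches_rule_oracle(scenario, k):
    P = build_partial_correlation(scenario, k, rho=-0.8, delay=5)
    expected = oracle_partial_correlation(scenario, k, -0.8, 5)
    np.testing.assert_array_equal(P, expected)


def test_baseline_is_identity_patterned():
    P = build_partial_correlation("baseline", 20, -0.8, 5)
    np.testing.assert_array_equal(P, np.eye(80))


def test_wcwt_delayed_entry_count():
    # k - delay couplings per affected block, none for worker fecundity
    k, delay = 20, 5
    P = build_partial_correlation("WCWT", k, -0.8, delay)
    layout = TraitIndexLayout(k)
    upper = np.triu(P, 1)
    assert np.count_nonzero(upper) == 3 * (k - delay)
    wf = layout.block_slice("worker", "fecundity")
    assert np.count_nonzero(P[wf, :] - np.eye(4 * k)[wf, :]) == 0


def test_zero_rho_collapses_to_baseline():
    base = build_partial_correlation("baseline", 20, -0.8, 5)
    for scenario in SCENARIOS[1:]:
        np.testing.assert_array_equal(
            build_partial_correlation(scenario, 20, 0.0, 5), base)
        arch = MutationArchitecture(scenario, k=20, rho=0.0)
        np.testing.assert_allclose(
            arch.Sigma, MutationArchitecture("baseline", k=20).Sigma, atol=1e-12)


def test_unknown_scenario_and_bad_delay_rejected():
    with pytest.raises(ConfigurationError):
        build_partial_correlation("nonsense", 20, -0.8, 5)
    with pytest.raises(ConfigurationError):
        build_partial_correlation("WCWT", 5, -0.8, 5)
    with pytest.raises(ConfigurationError):
        build_partial_correlation("WCWT", 20, -1.5, 5)


def test_layout_index_decode_bijection():
    layout = TraitIndexLayout(7)
    seen = set()
    for caste, trait in BLOCK_ORDER:
        for age in range(1, 8):
            flat = layout.index(caste, trait, age)
            assert layout.decode(flat) == (caste, trait, age)
            seen.add(flat)
    assert seen == set(range(28))


# ---------------------------------------------------------------------------
# Partial correlations -> covariance
# ---------------------------------------------------------------------------

def test_baseline_covariance_is_scaled_identity():
    P = build_partial_correlation("baseline", 20, -0.8, 5)
    Sigma = partial_to_covariance(P, 0.4)
    np.testing.assert_allclose(Sigma, 0.16 * np.eye(80), atol=1e-12)


def test_bcwt_pairwise_correlation_is_exact():
    # 2x2 precision blocks invert analytically: marginal corr equals rho
    arch = MutationArchitecture("BCWT", k=20, rho=-0.8, sigma=0.4)
    assert not arch.repair.fired
    layout = arch.layout
    for age in (1, 10, 20):
        i = layout.index("queen", "survival", age)
        j = layout.index("worker", "survival", age)
        corr = arch.Sigma[i, j] / 0.16
        assert corr == pytest.approx(-0.8, abs=1e-12)


@pytest.mark.parametrize("scenario", SCENARIOS)
def test_covariance_is_symmetric_psd_with_sigma_diag(scenario):
    arch = MutationArchitecture(scenario, k=20)
    S = arch.Sigma
    np.testing.assert_allclose(S, S.T, atol=1e-12)
    assert np.linalg.eigvalsh(S).min() >= -1e-10
    np.testing.assert_allclose(np.diag(S), 0.16, rtol=0.01)


@pytest.mark.parametrize("scenario", SCENARIOS[1:])
def test_covariance_sign_pattern_follows_partial_correlations(scenario):
    arch = MutationArchitecture(scenario, k=20, rho=-0.8)
    mask = (np.abs(arch.P) >= 0.1) & ~np.eye(80, dtype=bool)
    assert mask.any()
    assert np.all(np.sign(arch.Sigma[mask]) == np.sign(arch.P[mask]))


def test_repair_is_idempotent_on_psd_input():
    already = np.eye(10)
    already[0, 1] = already[1, 0] = 0.3
    out, info = nearest_correlation(already)
    assert not info.fired
    np.testing.assert_allclose(out, already, atol=1e-12)


def test_repair_fires_for_wcwt_chain_and_is_recorded():
    arch = MutationArchitecture("WCWT", k=20, rho=-0.8)
    assert arch.repair.fired
    assert arch.repair.frobenius_distance > 0


def test_partial_to_covariance_rejects_invalid_input():
    bad = np.eye(8)
    bad[0, 1] = 0.5  # asymmetric
    with pytest.raises(ConfigurationError):
        partial_to_covariance(bad, 0.4)
    bad2 = np.eye(8) * 2.0
    with pytest.raises(ConfigurationError):
        partial_to_covariance(bad2, 0.4)


@settings(deadline=None, max_examples=20, derandomize=True)
@given(scenario=st.sampled_from(SCENARIOS),
       k=st.sampled_from([6, 8, 20]),
       rho=st.floats(-0.9, 0.9))
def test_symmetry_preserved_through_chain(scenario, k, rho):
    P = build_partial_correlation(scenario, k, rho, delay=min(5, k - 1))
    Sigma = partial_to_covariance(P, 0.4)
    np.testing.assert_allclose(P, P.T, atol=1e-12)
    np.testing.assert_allclose(Sigma, Sigma.T, atol=1e-12)


# ---------------------------------------------------------------------------
# Mutation sampling
# ---------------------------------------------------------------------------

def test_sampler_moments_baseline(rng):
    arch = MutationArchitecture("baseline", k=20, b=-0.2, sigma=0.4)
    draws = sample_mutation(arch, rng, size=100_000)
    se = 0.4 / np.sqrt(100_000)
    assert np.all(np.abs(draws.mean(axis=0) + 0.2) < 3 * se)
    assert np.all(np.abs(draws.var(axis=0) / 0.16 - 1) < 0.05)


def test_sampler_pairwise_correlation_matches_sigma(rng):
    arch = MutationArchitecture("BCWT", k=20, rho=-0.8)
    layout = arch.layout
    draws = sample_mutation(arch, rng, size=100_000)
    i = layout.index("queen", "survival", 3)
    j = layout.index("worker", "survival", 3)
    implied = arch.Sigma[i, j] / np.sqrt(arch.Sigma[i, i] * arch.Sigma[j, j])
    emp = np.corrcoef(draws[:, i], draws[:, j])[0, 1]
    assert emp == pytest.approx(implied, abs=0.02)


def test_sampler_degenerate_sigma_returns_bias(rng):
    arch = MutationArchitecture("baseline", k=8, sigma=1e-12, b=-0.2)
    delta = sample_mutation(arch, rng)
    np.testing.assert_allclose(delta, -0.2, atol=1e-9)


def test_matrix_csv_export_roundtrip(tmp_path, rng):
    from casteage.architecture import export_matrix_csv

    arch = MutationArchitecture("BCWT", k=8)
    path = tmp_path / "P.csv"
    export_matrix_csv(arch.P, arch.layout, path)
    header = path.read_text().splitlines()[0].split(",")
    assert header[0] == "Q_surv_a1" and header[-1] == "W_fec_a8"
    back = np.loadtxt(path, delimiter=",", skiprows=1)
    np.testing.assert_allclose(back, arch.P)


def test_sampler_single_draw_shape_and_independence(rng):
    arch = MutationArchitecture("baseline", k=8)
    d1 = sample_mutation(arch, rng)
    d2 = sample_mutation(arch, rng)
    assert d1.shape == (32,)
    assert not np.allclose(d1, d2)
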