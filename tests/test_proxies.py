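"""Hand-evaluated proxy values and simplex property tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given

from tetramap import proxies
from tetramap.registry import COMPOUND_NAMES

from conftest import make_fa, simplex_vectors

P = "′"


# --------------------------------------------------------------------------
# MBT' family


def test_mbt_prime_all_ia():
    assert proxies.mbt_prime(make_fa(Ia=1.0)) == 1.0


def test_mbt_prime_all_iiia():
    assert proxies.mbt_prime(make_fa(IIIa=1.0)) == 0.0


def test_mbt_prime_hand_value():
    assert proxies.mbt_prime(make_fa(Ia=0.2, IIa=0.3, IIIa=0.5)) == \
        pytest.approx(0.2)


def test_mbt_prime_excludes_hexa_bc_series():
    # IIIb/IIIb'/IIIc/IIIc' are outside the printed compound set
    fa = make_fa(Ia=0.5, IIIbp=0.25, IIIcp=0.25)
    assert proxies.mbt_prime(fa) == pytest.approx(1.0)


def test_mbt_prime_6me_only_ib():
    assert proxies.mbt_prime_6me(make_fa(Ib=1.0)) == 1.0


def test_mbt_prime_6me_only_iia_prime():
    assert proxies.mbt_prime_6me(make_fa(IIap=1.0)) == 0.0


def test_mbt_prime_6me_hand_value():
    # IIIa (5-methyl) is not in the 6ME denominator
    fa = make_fa(Ia=0.4, IIap=0.4, IIIa=0.2)
    assert proxies.mbt_prime_6me(fa) == pytest.approx(0.5)


def test_mbt_prime_undefined_is_nan():
    fa = make_fa(IIIbp=1.0)  # empty denominator
    assert np.isnan(proxies.mbt_prime(fa))


# --------------------------------------------------------------------------
# IR6ME


def test_ir6me_all_six_methyl():
    assert proxies.ir_6me(make_fa(IIap=1.0)) == 1.0


def test_ir6me_symmetric_split():
    assert proxies.ir_6me(make_fa(IIa=0.5, IIap=0.5)) == pytest.approx(0.5)


def test_ir6me_default_denominator_includes_ia():
    fa = make_fa(Ia=0.5, IIap=0.25, IIIbp=0.25)
    assert proxies.ir_6me(fa) == pytest.approx(0.5)


def test_ir6me_penta_hexa_flag():
    fa = make_fa(Ia=0.5, IIap=0.25, IIIbp=0.25)
    assert proxies.ir_6me(fa, penta_hexa_only=True) == pytest.approx(1.0)


# --------------------------------------------------------------------------
# CBT' / CBT / pH


def test_cbt_prime_ratio_one():
    # numerator (IIa') and denominator (Ia+Ib) both equal 0.4
    fa = make_fa(Ia=0.3, Ib=0.1, IIap=0.4)
    assert proxies.cbt_prime(fa) == pytest.approx(0.0)


def test_cbt_prime_hand_value():
    fa = make_fa(Ia=0.5, Ib=0.3, Ic=0.2)
    assert proxies.cbt_prime(fa) == pytest.approx(-np.log10(0.2), abs=1e-9)
    assert proxies.cbt_prime(fa) == pytest.approx(0.69897, abs=1e-5)


def test_cbt_prime_log_decade():
    # numerator/denominator = 10
    fa = pd.Series(0.0, index=list(COMPOUND_NAMES))
    fa["IIa′"] = 10.0 / 11.0
    fa["Ia"] = 1.0 / 11.0
    assert proxies.cbt_prime(fa) == pytest.approx(-1.0)


def test_ph_linear_points():
    assert proxies.ph_from_cbt_prime(0.0) == pytest.approx(7.15)
    assert proxies.ph_from_cbt_prime(1.0) == pytest.approx(8.74)
    assert proxies.ph_from_cbt_prime(-1.0) == pytest.approx(5.56)


def test_cbt_classical_definition():
    fa = make_fa(Ia=0.4, IIa=0.1, Ib=0.05, IIb=0.45)
    expected = -np.log10((0.05 + 0.45) / (0.4 + 0.1))
    assert proxies.cbt(fa) == pytest.approx(expected)


# --------------------------------------------------------------------------
# temperature calibrations


def test_mat_mr_values():
    assert proxies.mat_mr(make_fa()) == pytest.approx(7.17)
    assert proxies.mat_mr(make_fa(Ia=1.0)) == pytest.approx(24.27)
    fa = make_fa(Ia=0.5, Ib=0.1, Ic=0.05, IIa=0.2)
    assert proxies.mat_mr(fa) == pytest.approx(14.31)


def test_mat_mr_simple_values():
    assert proxies.mat_mr_simple(make_fa()) == pytest.approx(5.58)
    assert proxies.mat_mr_simple(make_fa(Ia=1.0)) == pytest.approx(23.49)
    assert proxies.mat_mr_simple(make_fa(IIa=1.0)) == pytest.approx(-13.19)


def test_mat_ssm_values():
    assert proxies.mat_ssm(make_fa()) == pytest.approx(20.9)
    assert proxies.mat_ssm(make_fa(Ib=1.0)) == pytest.approx(32.1)
    assert proxies.mat_ssm(make_fa(IIa=0.5, IIap=0.5)) == pytest.approx(7.5)


def test_maat_weijers_values():
    # CBT = 0 (Ib+IIb = Ia+IIa) and MBT' = 0 is impossible simultaneously
    # with a real composition, so check the closed form against components
    fa = make_fa(Ia=0.25, Ib=0.25, IIa=0.25, IIb=0.25)
    expected = 0.81 - 5.67 * proxies.cbt(fa) + 31.0 * proxies.mbt_prime(fa)
    assert proxies.maat_weijers(fa) == pytest.approx(expected)


# --------------------------------------------------------------------------
# n-alkanes


def _alkanes(**conc):
    s = pd.Series(0.0, index=[f"C{n}" for n in range(23, 35)])
    for key, value in conc.items():
        s[key] = value
    return s


def test_cpi_flat_profile_is_one():
    flat = _alkanes(**{f"C{n}": 1.0 for n in range(23, 35)})
    assert proxies.cpi(flat, variant=1) == pytest.approx(1.0)
    assert proxies.cpi(flat, variant=2) == pytest.approx(1.0)


def test_cpi_hand_value():
    conc = {f"C{n}": 2.0 for n in range(23, 34, 2)}
    conc.update({f"C{n}": 1.0 for n in range(24, 33, 2)})
    assert proxies.cpi(_alkanes(**conc), variant=1) == pytest.approx(2.0)


def test_cpi_only_odd_is_undefined():
    odd = _alkanes(**{f"C{n}": 1.0 for n in range(23, 34, 2)})
    assert np.isnan(proxies.cpi(odd, variant=1))


def test_acl_single_homolog():
    assert proxies.acl(_alkanes(C29=5.0)) == pytest.approx(29.0)


def test_acl_equal_odd_homologs():
    eq = _alkanes(**{f"C{n}": 1.0 for n in (23, 25, 27, 29, 31, 33)})
    assert proxies.acl(eq) == pytest.approx(28.0)


def test_acl_weighted_mean():
    assert proxies.acl(_alkanes(C31=3.0, C27=1.0)) == pytest.approx(30.0)


# --------------------------------------------------------------------------
# suite & properties


def test_suite_flags_and_propagation():
    frame = pd.DataFrame([
        make_fa(Ia=0.2, Ic=0.1, IIap=0.5, IIIap=0.2),   # 6-methyl rich
        make_fa(Ia=0.5, Ib=0.3, IIa=0.2),               # no 6-methyls
    ])
    suite = proxies.compute_proxy_suite(frame)
    assert bool(suite["swc_interpretable"].iloc[0])
    assert not bool(suite["swc_interpretable"].iloc[1])
    assert np.isnan(suite["CBT_prime"].iloc[1])
    assert np.isnan(suite["pH"].iloc[1])
    assert np.isfinite(suite["MAT_mr"].iloc[1])


def test_ph_equals_linear_transform_of_cbt_prime():
    rng = np.random.default_rng(1)
    frame = pd.DataFrame(rng.dirichlet(np.ones(15), size=50),
                         columns=list(COMPOUND_NAMES))
    suite = proxies.compute_proxy_suite(frame)
    assert np.allclose(suite["pH"], 7.15 + 1.59 * suite["CBT_prime"])


@given(simplex_vectors())
def test_ratio_indices_in_unit_interval(vec):
    fa = pd.Series(vec, index=list(COMPOUND_NAMES))
    for fn in (proxies.mbt_prime, proxies.mbt_prime_6me, proxies.ir_6me):
        value = fn(fa)
        assert np.isnan(value) or 0.0 <= value <= 1.0


@given(simplex_vectors())
def test_cbt_prime_scale_invariant(vec):
    fa = pd.Series(vec, index=list(COMPOUND_NAMES))
    a = proxies.cbt_prime(fa)
    b = proxies.cbt_prime(fa * 7.3)
    assert (np.isnan(a) and np.isnan(b)) or a == pytest.approx(b, abs=1e-9)


def test_mat_mr_increasing_in_ia():
    fa = make_fa(Ia=0.2, IIa=0.3, IIIa=0.5)
    bumped = make_fa(Ia=0.3, IIa=0.3, IIIa=0.5)
    assert proxies.mat_mr(bumped) > proxies.mat_mr(fa)
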