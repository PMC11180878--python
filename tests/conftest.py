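"""Shared fixtures: the default synthetic study and its processed stages.

The expensive chain (generate -> filter -> TAMPOR -> proportions -> outlier
removal -> protected regression -> network) is built once per session and
reused by the unit and acceptance tests.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import vasc_protnet as vp

STUDY_SEED = 0
REGRESSION_SEED = 101

warnings.filterwarnings("ignore", category=RuntimeWarning)


@pytest.fixture(scope="session")
def study():
    return vp.generate_study(seed=STUDY_SEED)


@pytest.fixture(scope="session")
def filtered(study):
    return vp.filter_missingness(vp.zeros_to_missing(study.abundance))


@pytest.fixture(scope="session")
def tampor_result(study, filtered):
    return vp.tampor(filtered, study.meta)


@pytest.fixture(scope="session")
def corrected(tampor_result):
    return tampor_result.corrected


@pytest.fixture(scope="session")
def proportions(corrected, study):
    return vp.estimate_cell_proportions(corrected, study.markers)


@pytest.fixture(scope="session")
def outlier_flags(proportions):
    return vp.detect_endothelial_outliers(proportions)


@pytest.fixture(scope="session")
def regressed(corrected, study, proportions, outlier_flags):
    keep = [s for s in corrected.sample_ids if not outlier_flags.get(s, False)]
    trimmed = vp.AbundanceMatrix(corrected.data[keep], scale="log2")
    spec = vp.RegressionSpec(n_boot=1000, seed=REGRESSION_SEED)
    return vp.bootstrap_regress(trimmed, study.meta, study.traits, proportions, spec)


@pytest.fixture(scope="session")
def network_model(regressed):
    return vp.build_network(regressed)


@pytest.fixture(scope="session")
def bulk_corrected(study, outlier_flags):
    bulk = vp.filter_missingness(vp.zeros_to_missing(study.bulk_abundance))
    res = vp.tampor(bulk, study.meta)
    keep = [s for s in res.corrected.sample_ids if not outlier_flags.get(s, False)]
    return vp.AbundanceMatrix(res.corrected.data[keep], scale="log2")


def planted_recovery_ari(truth, assignments) -> float:
    """Adjusted Rand index between planted and detected modules, scored over
    planted-module members present in the analyzed matrix."""
    from sklearn.metrics import adjusted_rand_score

    labels = truth.module_labels.reindex(assignments.index)
    planted = labels != "background"
    return float(adjusted_rand_score(labels[planted], assignments[planted]))


@pytest.fixture(scope="session")
def recovery_ari(study, network_model):
    return planted_recovery_ari(study.truth, network_model.assignments)


def partial_correlation_given_diagnosis(y: np.ndarray, covariate: np.ndarray,
                                        is_ad: np.ndarray, is_psp: np.ndarray) -> float:
    """Correlation of y with a covariate after projecting out diagnosis."""
    obs = np.isfinite(y)
    if obs.sum() < 8:
        return np.nan
    D = np.column_stack([np.ones(obs.sum()), is_ad[obs], is_psp[obs]])
    ry = y[obs] - D @ np.linalg.lstsq(D, y[obs], rcond=None)[0]
    rc = covariate[obs] - D @ np.linalg.lstsq(D, covariate[obs], rcond=None)[0]
    if ry.std() == 0 or rc.std() == 0:
        return np.nan
    return float(np.corrcoef(ry, rc)[0, 1])
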