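import numpy as np
import pandas as pd
import pytest

import curiomap as cm
from curiomap.models import (
    SamplerSettings,
    coefficient_contrast,
    fit_exploration_model,
    fit_map_model,
    fit_moderation_model,
    hpdi,
    indirect_effect_draws,
    mediation,
)


def test_sampler_settings_presets():
    full = SamplerSettings()
    assert (full.chains, full.iterations, full.warmup) == (4, 4800, 2400)
    red = SamplerSettings.reduced()
    assert red.chains == 2 and red.iterations < full.iterations


@pytest.fixture(scope="module")
def exploration_fit(linear_design, quick_settings):
    return fit_exploration_model(linear_design, settings=quick_settings, seed=0)


def test_exploration_fit_structure(exploration_fit, quick_settings):
    fit = exploration_fit
    assert fit.outcomes == ["path_re", "head_re"]
    assert "curiosity_w:path_re" in fit.draws
    assert "resid_corr:path_re,head_re" in fit.draws
    n_kept = quick_settings.iterations - quick_settings.warmup
    assert fit.draws["curiosity_w:path_re"].shape == (quick_settings.chains, n_kept)
    summ = fit.summary()
    assert {"parameter", "mean", "hpdi_low", "hpdi_high", "rhat", "ess"} <= set(summ.columns)


def test_exploration_fit_recovers_signs(exploration_fit, linear_cohort):
    gt = linear_cohort["ground_truth"]
    fit = exploration_fit
    cur_path = hpdi(fit.flat("curiosity_w:path_re"))
    int_head = hpdi(fit.flat("interest_w:head_re"))
    assert cur_path.excludes_zero() and cur_path.mean > 0
    assert int_head.excludes_zero() and int_head.mean > 0
    assert cur_path.hpdi_low <= gt["b_cur_path"] <= cur_path.hpdi_high
    corr = hpdi(fit.flat("resid_corr:path_re,head_re"))
    assert corr.mean == pytest.approx(gt["resid_corr"], abs=0.1)


def test_contrast_linearity_and_self_contrast(exploration_fit):
    fit = exploration_fit
    c = coefficient_contrast(fit, "curiosity_w", "path_re", "head_re")
    manual = fit.flat("curiosity_w:path_re") - fit.flat("curiosity_w:head_re")
    assert c.mean == pytest.approx(manual.mean())
    self_c = coefficient_contrast(fit, "curiosity_w", "path_re", "path_re")
    assert self_c.mean == self_c.hpdi_low == self_c.hpdi_high == 0.0
    with pytest.raises(KeyError, match="curiosity_w"):
        coefficient_contrast(fit, "curiosity_w", "path_re", "composite")


def test_moderation_model_runs(linear_design, quick_settings, linear_cohort):
    fit = fit_moderation_model(linear_design, settings=quick_settings, seed=1)
    s = hpdi(fit.flat("trait_ST_cx_curiosity_w:path_re"))
    gt = linear_cohort["ground_truth"]
    assert s.hpdi_low <= gt["theta_st"] <= s.hpdi_high
    assert s.mean > 0


def test_moderation_requires_traits(linear_cohort, quick_settings):
    design = cm.build_design(linear_cohort["trials"])  # no traits
    with pytest.raises(ValueError, match="trait"):
        fit_moderation_model(design, settings=quick_settings, seed=0)


def test_map_model_recovers_path_coefficient(linear_design, quick_settings, linear_cohort):
    fit = fit_map_model(linear_design, settings=quick_settings, seed=2)
    gt = linear_cohort["ground_truth"]
    b = hpdi(fit.flat("path_re_w:composite"))
    sd = fit.flat("path_re_w:composite").std()
    assert abs(b.mean - gt["b_path_map"]) < 3 * sd
    assert b.excludes_zero() and b.mean > 0


def test_map_model_requires_composite(linear_cohort, quick_settings):
    design = cm.build_design(linear_cohort["trials"].drop(columns=["composite"]))
    with pytest.raises(ValueError, match="composite"):
        fit_map_model(design, settings=quick_settings, seed=0)


def test_constant_predictor_rejected(linear_design, quick_settings):
    bad = linear_design.copy()
    bad["duration_c"] = 0.0
    with pytest.raises(ValueError, match="constant"):
        fit_exploration_model(bad, settings=quick_settings, seed=0)


def test_constant_outcome_rejected(linear_design, quick_settings):
    bad = linear_design.copy()
    bad["head_re"] = 0.5
    with pytest.raises(ValueError, match="outcome"):
        fit_exploration_model(bad, settings=quick_settings, seed=0)


def test_indirect_effect_draws_is_drawwise_product():
    rng = np.random.default_rng(0)
    a = rng.normal(1.0, 2.0, 5000)  # skewed product distribution
    b = rng.normal(0.5, 1.5, 5000)
    prod = indirect_effect_draws(a, b)
    assert np.allclose(prod, a * b)
    # the mean of products differs from the product of means when draws vary
    assert prod.mean() != pytest.approx(a.mean() * b.mean(), abs=1e-6)
    with pytest.raises(ValueError, match="align"):
        indirect_effect_draws(a[:10], b[:20])


def test_mediation_on_linear_truth(linear_design, quick_settings, linear_cohort):
    med = mediation(linear_design, settings=quick_settings, seed=3)
    gt = linear_cohort["ground_truth"]
    sd = med.indirect_draws.std()
    assert abs(med.indirect.mean - gt["indirect_effect"]) < 3 * sd
    assert med.indirect.excludes_zero()
    assert np.allclose(
        med.indirect_draws,
        med.mediator_fit.flat("curiosity_w:path_re")
        * med.outcome_fit.flat("path_re_w:composite"),
    )


def test_min_structure_check(quick_settings):
    tiny = pd.DataFrame(
        {
            "participant_id": ["P1", "P2"],
            "room_id": ["R1", "R1"],
            "curiosity": [4, 6], "interest": [5, 5], "duration_s": [10.0, 12.0],
            "path_re": [0.4, 0.5], "head_re": [0.5, 0.6],
        }
    )
    with pytest.warns(UserWarning, match="single trial"):
        design = cm.build_design(tiny)
    with pytest.raises(ValueError, match="at least 2 participants"):
        fit_exploration_model(design, settings=quick_settings, seed=0)
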