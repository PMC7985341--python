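"""Shared fixtures: the default phantom, its distorted acquisitions, and the
(expensive) correction results, built once per session."""
import warnings

import numpy as np
import pytest

from epiwarp import fieldmap, phantom, topup
from epiwarp.warp import EPIGeometry, PEResamplePlan, db0_to_vsm


@pytest.fixture(scope="session")
def geom():
    # acquisition constants of the emulated protocol: 2.5 mm PE voxels,
    # 78 echoes at 0.57 ms nominal spacing, 2x in-plane acceleration
    return EPIGeometry(voxel_size_pe=2.5, n_pe=78, echo_spacing_s=0.57e-3,
                       accel=2, pe_axis=1, pe_polarity=+1)


@pytest.fixture(scope="session")
def spec():
    return phantom.PhantomSpec(seed=0)


@pytest.fixture(scope="session")
def phantom_data(spec):
    return phantom.make_phantom(spec)


@pytest.fixture(scope="session")
def truth(phantom_data):
    return phantom_data[1]


@pytest.fixture(scope="session")
def structural(phantom_data):
    return phantom_data[0]


@pytest.fixture(scope="session")
def field(spec):
    return phantom.make_field(spec)


@pytest.fixture(scope="session")
def true_vsm(field, geom):
    return db0_to_vsm(field, geom)


@pytest.fixture(scope="session")
def baseline(truth, spec):
    return phantom.epi_baseline(truth.tissue_labels, spec)


@pytest.fixture(scope="session")
def clean_pair(baseline, true_vsm, geom):
    """Noise-free AP/PA volumes of the EPI baseline under the true field."""
    ap = PEResamplePlan(true_vsm, geom.with_polarity(+1), "apply")(baseline)
    pa = PEResamplePlan(true_vsm, geom.with_polarity(-1), "apply")(baseline)
    return ap, pa


@pytest.fixture(scope="session")
def noisy_run(truth, field, geom, spec, baseline):
    """Default study conditions: 2% noise, seed 0, block-design task run."""
    design = phantom.TaskDesign()
    noise_sd = 0.02 * float(baseline[truth.brain_mask].mean())
    run = phantom.synth_epi_run(truth, field, geom, design, spec,
                                noise_sd=noise_sd, seed=0)
    return run


@pytest.fixture(scope="session")
def noisy_pair(noisy_run):
    ap_mid = np.asarray(noisy_run.ap[..., noisy_run.ap.shape[-1] // 2], float)
    pa_last = np.asarray(noisy_run.pa[..., -1], float)
    return ap_mid, pa_last


@pytest.fixture(scope="session")
def topup_noisy(noisy_pair, geom):
    """Reversed-PE estimate on the 2%-noise pair (shared: slow)."""
    pair = topup.ReversedPair(ap_volume=noisy_pair[0], pa_volume=noisy_pair[1],
                              geom=geom)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = topup.estimate_field_topup(pair)
    return pair, result


@pytest.fixture(scope="session")
def gre_noisefree(structural, field, truth, clean_pair, geom):
    """GRE chain on noise-free images without smoothing (exact recovery)."""
    dual = phantom.synth_dual_echo(structural, field, noise_sd=0.0)
    corrected, f_est, v_est = fieldmap.correct_gre(
        clean_pair[0], dual, geom, fwhm_mm=0.0, mask=truth.brain_mask)
    return corrected, f_est, v_est


@pytest.fixture(scope="session")
def gre_snr50(structural, field, truth, noisy_pair, geom):
    """GRE chain at SNR 50 with the default 4 mm smoothing."""
    noise_sd = float(structural[truth.brain_mask].mean()) / 50.0
    dual = phantom.synth_dual_echo(structural, field, noise_sd=noise_sd, seed=0)
    corrected, f_est, v_est = fieldmap.correct_gre(noisy_pair[0], dual, geom,
                                                   fwhm_mm=4.0)
    return corrected, f_est, v_est


@pytest.fixture(scope="session")
def reduced_report():
    """One full pipeline run on a shortened series (shared across tests)."""
    from epiwarp import pipeline
    cfg = pipeline.RunConfig(n_volumes=64, ica_components=4, seed=0,
                             topup_max_iter=8)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return pipeline.full_run(cfg), cfg
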