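"""Shared fixtures: small synthetic samples and instrument configurations."""

import pytest
from hypothesis import settings

from acquisim import acquire, simulate, targets as targets_mod
from acquisim._seeds import derive_seed

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def short_model():
    """Signal model for a 3-minute test gradient."""
    return simulate.SignalModel(gradient_min=3.0)


@pytest.fixture(scope="session")
def small_mixture():
    """60 background peptides on a 3-minute gradient."""
    bg = simulate.generate_peptidome(60, seed=5, gradient_min=3.0)
    return simulate.SampleMixture(bg, 1.0, seed=11)


@pytest.fixture(scope="session")
def spiked_setup():
    """Background + diluted spike with a scheduled inclusion list (3-min gradient)."""
    gradient = 3.0
    bg = simulate.generate_peptidome(60, seed=derive_seed(0, "bg"), gradient_min=gradient)
    spike = simulate.generate_peptidome(
        10, seed=derive_seed(0, "spike"), gradient_min=gradient,
        source="spike", target_fraction=1.0,
    )
    target_list = [
        targets_mod.TargetPeptide(p.sequence, "TAA", rt_pred=p.rt_apex)
        for p in spike
    ]
    sil = targets_mod.schedule(
        target_list, halfwidth_min=1.0, gradient_min=gradient
    )
    mixture = simulate.make_dilution_series(bg, spike, [1 / 16], seed=3)[0]
    model = simulate.SignalModel(gradient_min=gradient)
    return mixture, sil, model, {t.sequence for t in target_list}
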