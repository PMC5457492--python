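"""Shared fixtures: small simulated experiments reused across test modules.

Everything is generated at run time from fixed seeds; nothing is read
from disk except what the tests themselves write to tmp paths.
"""

import pytest

from duoscreen import SimConfig, call_essential, score_genes, screen_lfc, simulate_experiment


@pytest.fixture(scope="session")
def clean_exp():
    """A small clean paired screen: no amplicons, no bidirectional pairs."""
    cfg = SimConfig(n_genes=60, n_essential=12, n_aavs1=80, n_nontargeting=120)
    return simulate_experiment(cfg, seed=11)


@pytest.fixture(scope="session")
def confound_exp():
    """A small paired screen with both artifact mechanisms switched on."""
    cfg = SimConfig.confound(
        n_genes=48, n_essential=10, n_amplified=6, n_bidirectional_pairs=5,
        n_aavs1=80, n_nontargeting=120,
    )
    return simulate_experiment(cfg, seed=23)


@pytest.fixture(scope="session")
def clean_calls(clean_exp):
    """Per-modality fold-changes and essential-gene calls for clean_exp."""
    out = {}
    for modality, mode in (("cas9", "exon"), ("krab_dcas9", "primary_tss")):
        fc = screen_lfc(clean_exp.counts[modality], clean_exp.library)
        scores = score_genes(fc, clean_exp.library, mode)
        out[modality] = (fc, scores, call_essential(scores))
    return out
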