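"""Shared fixtures: a small synthetic study for fast unit tests and the
full-scale contact-calling scenario shared by the calibration and
planted-loop recovery checks."""

from __future__ import annotations

import numpy as np
import pytest

from evoreg.backgrounds import sample_gc_length_matched
from evoreg.hic import fit_null, profiles_for_intervals
from evoreg.simulate import (
    SynthConfig,
    make_contact_map,
    make_expression_atlases,
    make_genome_and_annotation,
)


def small_config(seed: int = 11) -> SynthConfig:
    """Desk-scale config: 2 x 3 Mb, a few hundred elements, 30 loops."""
    return SynthConfig(
        seed=seed,
        chrom_lengths={"chr1": 3_000_000, "chr2": 3_000_000},
        n_elements={"HAR": 300, "HGE_FB": 150, "HGE_AB": 100, "HLE": 100},
        n_genes=120,
        n_loops=30,
        n_neutral_peaks=300,
        n_orthologs=800,
        dz_set_size=150,
        bp_set_size=80,
        prenatal_set_size=120,
        marker_set_size=60,
        module_set_size=120,
        dnds_set_size=120,
    )


@pytest.fixture(scope="session")
def small_study():
    return make_genome_and_annotation(small_config())


@pytest.fixture(scope="session")
def small_contacts(small_study):
    contacts, loops = make_contact_map(small_study.config, small_study)
    return contacts, loops


@pytest.fixture(scope="session")
def small_expression():
    return make_expression_atlases(small_config())


@pytest.fixture(scope="session")
def hic_scenario():
    """Full-size scenario: 2 x 20 Mb genome, 2737 elements, 100 planted
    loops at 3x the decay mean, with a Weibull null fitted from 2,000
    GC/length-matched control profiles."""
    cfg = SynthConfig(seed=7)
    study = make_genome_and_annotation(cfg)
    contacts, loops = make_contact_map(cfg, study)
    har = study.elements["HAR"]
    matched = sample_gc_length_matched(har, study.genome, reps=40, seed=7)
    rng = np.random.default_rng(7)
    idx = rng.choice(len(matched.pooled), size=2000, replace=False)
    profiles = [
        p for _, p in profiles_for_intervals(contacts, matched.pooled.subset(idx))
    ]
    null = fit_null(profiles, max_obs=5000, rng=rng)
    return {
        "config": cfg,
        "study": study,
        "contacts": contacts,
        "loops": loops,
        "matched": matched,
        "null": null,
    }
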