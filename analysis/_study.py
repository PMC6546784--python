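"""Shared helper for the numbered analysis scripts: deterministic study
regeneration so each script can run standalone."""

from __future__ import annotations

import sys
from pathlib import Path

REPO = Path(__file__).resolve().parent.parent
RESULTS = REPO / "results"
SCRATCH = REPO / "scratch"

sys.path.insert(0, str(REPO / "src"))

from evoreg.simulate import (  # noqa: E402
    SynthConfig,
    make_contact_map,
    make_expression_atlases,
    make_genome_and_annotation,
)

SEED = 0


def get_study(seed: int = SEED, with_contacts: bool = True,
              with_expression: bool = True):
    cfg = SynthConfig(seed=seed)
    study = make_genome_and_annotation(cfg)
    contacts = loops = expr = None
    if with_contacts:
        contacts, loops = make_contact_map(cfg, study)
    if with_expression:
        expr = make_expression_atlases(
            cfg, gene_ids=[g.gene_id for g in study.genes], truth=study.truth
        )
    return cfg, study, contacts, loops, expr


def write_table(df, name: str) -> Path:
    RESULTS.mkdir(exist_ok=True)
    path = RESULTS / name
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return path


def fit_null_from_controls(contacts, study, seed, n_controls: int = 2000):
    """Weibull null from GC/length-matched control profiles (40 per element)."""
    import numpy as np

    from evoreg.backgrounds import sample_gc_length_matched
    from evoreg.hic import fit_null, profiles_for_intervals

    har = study.elements["HAR"]
    matched = sample_gc_length_matched(har, study.genome, reps=40, seed=seed)
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(matched.pooled), size=n_controls, replace=False)
    profiles = [
        p for _, p in profiles_for_intervals(contacts, matched.pooled.subset(idx))
    ]
    return fit_null(profiles, max_obs=5000, rng=rng)


def call_class(contacts, null, elems, fdr: float = 0.01):
    """Score every candidate bin of every element and BH-correct."""
    import pandas as pd

    from evoreg.hic import correct_and_call, interaction_pvalues, profiles_for_intervals

    frames = [
        interaction_pvalues(prof, null, name)
        for name, prof in profiles_for_intervals(contacts, elems)
    ]
    return correct_and_call(pd.concat(frames, ignore_index=True), fdr)
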