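"""Cross-species regulation statistics on the two-species atlases.

Per-gene stage Z-scores in each species; delta expression Z at the
event-score-matched stages (planted set: +0.128); breakpoint-shift rank test
(planted set: -0.05, i.e. earlier in human); log2(dN/dS) purifying-selection
contrast; and co-expression module membership enrichment (planted module
OR 7).
"""

import pandas as pd
from _study import get_study, write_table

from evoreg.crossspecies import (
    DEFAULT_STAGE_PAIRS,
    breakpoint_shift,
    delta_z,
    dnds_contrast,
    module_enrichment,
    stage_zscores,
)


def main() -> None:
    _, study, _, _, expr = get_study(with_contacts=False)
    hz, _ = stage_zscores(expr.human_stages)
    mz, _ = stage_zscores(expr.macaque_stages)
    dz = delta_z(hz, mz, DEFAULT_STAGE_PAIRS, expr.truth.dz_genes)
    bp_bg = [g for g in expr.ortholog_ids if g not in set(expr.truth.bp_genes)]
    bp = breakpoint_shift(expr.breakpoints, expr.truth.bp_genes, bp_bg)
    dn_bg = [g for g in expr.ortholog_ids if g not in set(expr.truth.dnds_genes)]
    dn = dnds_contrast(expr.dnds, expr.truth.dnds_genes, dn_bg,
                       species_pair="macaque")
    mods = module_enrichment(expr.truth.module_set_genes, expr.modules,
                             expr.ortholog_ids)
    write_table(mods, "06_module_enrichment.tsv")
    df = pd.DataFrame(
        [
            {"statistic": "delta_z_set_shift",
             "value": dz.set_mean - dz.background_mean, "p": dz.p_value,
             "planted": expr.truth.dz_shift},
            {"statistic": "breakpoint_median_shift",
             "value": bp["median_difference"], "p": bp["p_value"],
             "planted": expr.truth.bp_shift},
            {"statistic": "dnds_set_median_log2", "value": dn["median_set_log2"],
             "p": dn["p_value"], "planted": None},
            {"statistic": "module_top_or", "value": mods.iloc[0]["odds_ratio"],
             "p": mods.iloc[0]["q_value"], "planted": expr.truth.module_or},
        ]
    )
    path = write_table(df, "06_cross_species.tsv")
    print(f"cross-species statistics -> {path}")
    print(df.to_string(index=False))
    print(
        f"\nbreakpoint direction: {bp['direction']} "
        f"(negative shift = earlier developmental change in human); "
        f"top module is {mods.iloc[0]['module']}."
    )


if __name__ == "__main__":
    main()
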