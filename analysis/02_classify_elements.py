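"""Classify elements against gene features (coding vs noncoding).

Elements in exons, UTRs, 1 kb promoters or 1 kb downstream flanks are
"coding" and will be assigned to their host genes directly; intronic and
intergenic elements go through the chromatin-interaction route.  The
sequence-accelerated class sits on conserved islands and is therefore mostly
intergenic/intronic here, as in real data.
"""

import pandas as pd
from _study import get_study, write_table

from evoreg.intervals import classify_elements


def main() -> None:
    _, study, _, _, _ = get_study(with_contacts=False, with_expression=False)
    rows = []
    for cls_, elems in study.elements.items():
        cats = classify_elements(elems, study.genes)
        counts = pd.Series([c.category for c in cats]).value_counts()
        coding = sum(c.coding for c in cats)
        for cat, n in counts.items():
            rows.append({"class": cls_, "category": cat, "n": int(n)})
        rows.append({"class": cls_, "category": "ALL_CODING", "n": int(coding)})
        rows.append({"class": cls_, "category": "ALL_NONCODING",
                     "n": len(elems) - int(coding)})
    df = pd.DataFrame(rows)
    path = write_table(df, "02_classification_counts.tsv")
    print(f"classification counts -> {path}")
    wide = df.pivot(index="category", columns="class", values="n").fillna(0).astype(int)
    print(wide.to_string())


if __name__ == "__main__":
    main()
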