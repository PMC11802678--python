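"""Needle-composition response to ozonation: class percentages and ANOVA.

Generates synthetic GC–MS peak tables with the study's compound roster and
a monoterpene-depletion / C₇₋₈-oxidation-product-accumulation effect across
ozonation categories (A ambient, B 3 h, C 10 h), then tests each compound
class with one-way ANOVA.  Writes results/gcms_anova.csv.
"""

import argparse
from pathlib import Path

from oxstab.gcms_composition import aggregate_classes, class_anova_table
from oxstab.synthetic import SyntheticConfig, generate_peak_table


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--effect", type=float, default=1.0,
                    help="category effect scale (0 = null)")
    args = ap.parse_args()

    table = generate_peak_table(SyntheticConfig(seed=args.seed),
                                effect=args.effect)
    profiles = aggregate_classes(table)
    anova = class_anova_table(profiles)
    out = Path("results")
    out.mkdir(exist_ok=True)
    profiles.to_csv(out / "gcms_profiles.csv", index=False)
    anova.to_csv(out / "gcms_anova.csv", index=False)
    print(anova.round(4).to_string(index=False))
    sig = anova.loc[anova["significant"], "compound_class"].tolist()
    print(f"\nClasses responding to ozonation at p < 0.05: {sig} "
          "(monoterpenes decline, oxygenated C7-8 products accumulate; "
          "sesquiterpenes stay stable).")


if __name__ == "__main__":
    main()
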