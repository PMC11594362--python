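"""Generate the synthetic replicated survey and its degraded variant.

Produces a clean community dataset (20 species x 200 sites x 4 replicates,
one latent site factor) and a survey-degraded copy in which a fraction of
species is recorded at most twice and a fraction of sites loses half its
visit effort — the raw material for the occupancy and rarity stages.
Writes both as dataset directories plus a summary table under results/.
"""

from pathlib import Path

import pandas as pd

from odorare.simulate import (
    CommunityConfig,
    degrade_to_survey,
    simulate_community,
    write_dataset,
)

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cfg = CommunityConfig(seed=1)
    clean = simulate_community(cfg)
    degraded = degrade_to_survey(clean, species_dropout=0.25, lotic_bias=0.4, seed=2)

    write_dataset(clean, OUT / "survey_clean")
    write_dataset(degraded, OUT / "survey_degraded")

    rows = []
    for name, ds in [("clean", clean), ("degraded", degraded)]:
        det = ds.y.sum(axis=(1, 2))
        rows.append({
            "dataset": name,
            "species": ds.y.shape[0],
            "sites": ds.y.shape[1],
            "replicates": ds.y.shape[2],
            "total_detections": int(ds.y.sum()),
            "species_below_filter": int((det < 3).sum()),
            "mean_visits": float(ds.visits.mean()),
        })
    table = pd.DataFrame(rows)
    OUT.mkdir(exist_ok=True)
    table.to_csv(OUT / "01_survey_summary.csv", index=False)
    print(table.to_string(index=False))
    print("\nDegradation pushed "
          f"{rows[1]['species_below_filter'] - rows[0]['species_below_filter']} "
          "additional species below the 3-detection modelling filter.")


if __name__ == "__main__":
    main()
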