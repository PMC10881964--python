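#!/usr/bin/env python
"""Phenotypic clustering of multi-environment fitness profiles.

Plants three profile archetypes (600 lineages, component noise SD 0.5 across
10 environments), recovers them by average-linkage agglomerative clustering,
and classifies each cluster as knockout-like (close to a curated gene
knockout profile) or novel.  Writes results/clusters/.
"""

from pathlib import Path

import pandas as pd

from tnlineage import scenarios

ROOT = Path(__file__).resolve().parent.parent / "results"
SEED = 5


def main():
    ari, coverage, kinds = scenarios.cluster_recovery(seed=SEED)
    out = ROOT / "clusters"
    out.mkdir(parents=True, exist_ok=True)
    rows = [{"archetype": k, "kind": v[0], "min_distance_to_gene": v[1]}
            for k, v in sorted(kinds.items())]
    pd.DataFrame(rows).to_csv(out / "cluster_classification.tsv", sep="\t",
                              index=False)
    print(f"co-clustering agreement (ARI): {ari:.3f}; "
          f"{coverage:.1%} of lineages clustered")
    for r in rows:
        print(f"archetype {r['archetype']}: {r['kind']} "
              f"(min distance to a gene profile: {r['min_distance_to_gene']:.2f})")
    print("archetype 0 was planted to match a curated gene knockout; "
          "archetypes 1-2 have no gene counterpart and come out novel")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
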