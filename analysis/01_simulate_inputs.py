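#!/usr/bin/env python
"""Generate the synthetic study inputs used by the downstream analyses.

Writes under results/data/:
  sites.tsv            quantified SILAC phosphosite table (2000 sites, 4
                       replicates, 40% Cdk1-motif, 10% of motif sites spiked
                       at +1.5 log2 in the high Cyclin A channel)
  network.tsv          weighted interaction network with two planted
                       6-member complexes among 50 proteins
  planted_clusters.json  the planted memberships (ground truth for 03)
  traces.csv           photoactivation time courses: 15 prometaphase-like
                       cells (k-MT half-life 180 s) and 15 metaphase-like
                       cells (420 s), sampled every 15 s for 4 min
"""

import argparse
import json
from pathlib import Path

from phosphoflux import fdapa as fd
from phosphoflux import silac
from phosphoflux.synthetic import (
    FdapaSimConfig,
    SilacSimConfig,
    generate_fdapa_traces,
    generate_silac_table,
    generate_toy_network,
)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out", type=Path, default=Path("results/data"))
    args = parser.parse_args()
    out = args.out
    out.mkdir(parents=True, exist_ok=True)

    table = generate_silac_table(
        SilacSimConfig(
            n_sites=2000, frac_cdk1_motif=0.4, frac_spiked=0.1, effect_log2=1.5,
            replicate_sd=0.3, mixing_shift=0.2, seed=args.seed,
        )
    )
    silac.write_site_table(table, out / "sites.tsv")
    print(f"sites.tsv: {len(table)} sites, {int(table.is_spiked.sum())} spiked")

    planted = [[f"N{i:03d}" for i in range(6)], [f"N{i:03d}" for i in range(6, 12)]]
    edges = generate_toy_network(50, planted, p_in=0.9, p_out=0.02, seed=args.seed + 4)
    edges.to_csv(out / "network.tsv", sep="\t", index=False, header=False)
    (out / "planted_clusters.json").write_text(json.dumps(planted) + "\n")
    print(f"network.tsv: {len(edges)} edges, 2 planted 6-member complexes")

    pro, _ = generate_fdapa_traces(
        FdapaSimConfig(t_half_slow=180, n_cells=15, phase="prometaphase", seed=args.seed + 2)
    )
    meta, _ = generate_fdapa_traces(
        FdapaSimConfig(t_half_slow=420, n_cells=15, phase="metaphase", seed=args.seed + 102)
    )
    fd.write_traces(pro + meta, out / "traces.csv")
    print(f"traces.csv: {len(pro) + len(meta)} cells "
          "(15 prometaphase-like at 180 s, 15 metaphase-like at 420 s)")


if __name__ == "__main__":
    main()
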