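"""Sex-stratified Spearman/BH-FDR correlation networks and their comparison.

Builds the male-only and female-only trait networks (edges at BH q <= 0.05),
writes GraphML and TSV edge lists, and reports the structural comparison:
which networks link injury to pain endpoints (week-6 withdrawal threshold)
versus structural endpoints (height change, degeneration grade).
"""
import json
from pathlib import Path

import networkx as nx

from discnet import io as dio
from discnet.network import compare_networks, default_trait_classes, network_from_table
from discnet.pipeline import EDGES_OF_INTEREST, edge_list, reduce_dataset, trait_tables

STUDY = Path("results/study")


def main() -> None:
    ds = dio.read_dataset(STUDY / "dataset")
    tables = trait_tables(ds, reduce_dataset(ds))
    nets = {}
    for sex, tbl in tables.items():
        g, *_ = network_from_table(tbl, alpha=0.05,
                                   node_classes=default_trait_classes())
        nets[sex] = g
        nx.write_graphml(g, STUDY / f"network_{sex}.graphml")
        edge_list(g).to_csv(STUDY / f"edges_{sex}.tsv", sep="\t", index=False)
        print(f"{sex}: {g.number_of_edges()} edges over {g.number_of_nodes()} traits; "
              f"injury degree {g.degree('injury')}")
    report = compare_networks(nets["male"], nets["female"], EDGES_OF_INTEREST)
    (STUDY / "network_comparison.json").write_text(
        json.dumps(report, indent=2, sort_keys=True, default=str))
    print(f"edge overlap (Jaccard over shared traits): {report['jaccard']:.3f}")
    for name, flags in report["edges_of_interest"].items():
        print(f"  {name}: male={flags['in_a']} female={flags['in_b']}")


if __name__ == "__main__":
    main()
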