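"""Catalog the cyst topologies reachable by synchronous division rounds.

Starting from the 2-cell cyst there is a single 4-cell topology (the linear
chain); from the chain, 3 eight-cell topologies (one maximally branched);
and from the maximally branched 8-cell cyst, 36 sixteen-cell topologies, of
which again exactly one is maximally branched.  Writes the class table to
results/topology_classes.csv.
"""

from pathlib import Path

import pandas as pd

from fusomekit import topology as tp

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    rows = []
    for label, start_n in (("2cell", 2), ("4cell", 4), ("8cell-max", 8)):
        start = tp.canonical_max_branched(start_n)
        res = tp.enumerate_topologies(start)
        print(
            f"{label} -> {2 * start_n} cells: {res.n_labeled} labeled outcomes, "
            f"{res.n_classes} topology classes, {res.n_max_branched} maximally branched"
        )
        for i, tree in enumerate(res.representatives):
            rows.append(
                {
                    "start": label,
                    "class_id": i,
                    "n_cells": tree.n_cells,
                    "max_branched": tp.is_max_branched(tree),
                    "degree_sequence": "-".join(map(str, tree.degree_sequence())),
                    "newick": tree.newick(),
                }
            )
    table = pd.DataFrame(rows)
    table.to_csv(OUT / "topology_classes.csv", index=False)
    print(f"wrote {len(table)} class representatives to {OUT / 'topology_classes.csv'}")


if __name__ == "__main__":
    main()
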