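"""Build cross-linked nanogel network models for all four compositions.

Runs the full construction protocol (four DP-20 chains with 0/1/3/4 AAc
units + 50 BIS packed at 0.8 g cm^-3, iterative 3.5→5.0 Å template
cross-linking toward 80% conversion, unreacted-BIS pruning) for each
composition under both protonation models, and records the per-cycle
conversion history.

Writes results/network_builds.csv and one representative structure,
results/network_CA-15_acidic.pdb.
"""

import sys
from pathlib import Path

import pandas as pd

from gelmesh.io import write_structure
from gelmesh.topology import ACIDIC, BASIC, build_network

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main(seed: int = 1) -> None:
    RESULTS.mkdir(exist_ok=True)
    rows = []
    for pct in (0, 5, 15, 20):
        for prot in (ACIDIC, BASIC):
            net, rep = build_network(aac_mol_pct=pct, protonation=prot, seed=seed)
            rows.append({
                "aac_mol_pct": pct,
                "protonation": prot.mode,
                "n_atoms": net.n_atoms,
                "n_bonds": len(net.bonds),
                "final_conversion": round(rep.final_conversion, 4),
                "ladder_exhausted": rep.ladder_exhausted,
                "pruned_bis": rep.pruned_bis,
                "n_cycles": len(rep.cycles),
            })
            if pct == 15 and prot.mode == "acidic":
                write_structure(net, RESULTS / "network_CA-15_acidic.pdb")
    df = pd.DataFrame(rows)
    df.to_csv(RESULTS / "network_builds.csv", index=False)
    print(df.to_string(index=False))
    print("\nConversion is monotone within each run; ladder-exhausted builds "
          "terminate below the 80% target because the deterministic surrogate "
          "relaxation cannot thermally shuffle new reactive contacts into range.")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
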