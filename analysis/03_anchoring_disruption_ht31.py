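#!/usr/bin/env python
"""Disruption of PKA anchoring (Ht31-peptide mimic).

With adenylate cyclase anchored in the spine heads, redistributing the PKA
pool uniformly over the morphology reduces window-averaged phosphoThr34
DARPP-32 and phosphoSer845 GluA1 by roughly 30%.
"""

import argparse
import json
from pathlib import Path

from spinesim.scenarios import run_scenario


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--preset", default="desk", choices=["desk", "paper"])
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    res = run_scenario("ht31_uniform", preset=args.preset, seed=args.seed)
    print(f"pThr34: anchored {res['anchored.pThr34_avg_nM']:.1f} nM, "
          f"uniform {res['uniform.pThr34_avg_nM']:.1f} nM "
          f"-> {res['percent_reduction_pThr34']:.1f}% reduction")
    print(f"pSer845: anchored {res['anchored.pSer845_avg_percent']:.2f}%, "
          f"uniform {res['uniform.pSer845_avg_percent']:.2f}% "
          f"-> {res['percent_reduction_pSer845']:.1f}% reduction")
    args.out.mkdir(parents=True, exist_ok=True)
    (args.out / "ht31_uniform.json").write_text(json.dumps(res, indent=1,
                                                           default=float))


if __name__ == "__main__":
    main()
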