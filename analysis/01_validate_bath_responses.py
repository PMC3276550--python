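#!/usr/bin/env python
"""Bath-application validation of the signaling model.

Clamps dopamine (10 uM), calcium (600 nM), or both over the whole morphology
and reports the canonical dose responses: phosphoThr34 DARPP-32 rises ~6-fold
within 2 min of dopamine, phosphoThr75 falls to ~60% of basal, and
phosphoSer845 GluA1 rises ~8-fold within 5-10 min; calcium dephosphorylates
both DARPP-32 sites; pairing blunts the dopamine response.
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

    out = {}
    for name in ("validation_da_bath", "validation_ca_bath", "validation_da_ca"):
        res = run_scenario(name, preset=args.preset, seed=args.seed)
        out[name] = res
        print(f"== {name}")
        for k in ("pThr34_fold_2min", "pThr75_percent_of_basal",
                  "pSer845_fold_5to10min"):
            print(f"   {k}: {res[k]:.3g}")

    da = out["validation_da_bath"]
    print(f"\nDopamine bath: pThr34 x{da['pThr34_fold_2min']:.2f} in 2 min, "
          f"pThr75 at {da['pThr75_percent_of_basal']:.0f}% of basal, "
          f"pSer845 x{da['pSer845_fold_5to10min']:.2f} at 5-10 min.")
    args.out.mkdir(parents=True, exist_ok=True)
    (args.out / "validation.json").write_text(json.dumps(out, indent=1,
                                                         default=float))
    print(f"wrote {args.out / 'validation.json'}")


if __name__ == "__main__":
    main()
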