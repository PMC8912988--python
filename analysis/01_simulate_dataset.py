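"""Generate the six-condition synthetic study dataset.

Writes raw EEMs, fresh blanks, absorbance spectra and growth curves for
SFW0-SFW5 (3 replicates x 15 time points each) under scratch/dataset,
together with dataset.yaml (run inputs) and manifest.json (ground truth).
"""

import argparse
from pathlib import Path

from afom.synth import SAMPLING_SCHEDULE, simulate_condition_set

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out", type=Path, default=ROOT / "scratch" / "dataset")
    args = parser.parse_args()

    out = simulate_condition_set(args.out, master_seed=args.seed)
    eems = sorted(out.glob("SFW*/rep*/eem_t*.csv"))
    print(f"dataset written to {out}")
    print(f"  {len(eems)} sample EEMs (6 conditions x 3 replicates x "
          f"{len(SAMPLING_SCHEDULE)} time points), each with a fresh blank "
          "and absorbance spectrum")
    print("  ground truth in manifest.json; run inputs in dataset.yaml")


if __name__ == "__main__":
    main()
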