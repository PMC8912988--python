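"""Correct every raw EEM to a QSU-normalized analysis window.

Applies inner-filter correction, fresh-blank subtraction, Rayleigh
masking, cropping to excitation 240-490 nm / emission 250-500 nm, and
quinine sulfate normalization; writes corrected EEMs under
scratch/corrected mirroring the dataset layout.
"""

import argparse
from pathlib import Path

from afom.pipeline import run_preprocess

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--dataset", type=Path, default=ROOT / "scratch" / "dataset")
    parser.add_argument("--out", type=Path, default=ROOT / "scratch" / "corrected")
    args = parser.parse_args()

    written = run_preprocess(args.dataset, args.out)
    print(f"corrected {len(written)} EEMs into {args.out}")


if __name__ == "__main__":
    main()
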