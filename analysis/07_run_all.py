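#!/usr/bin/env python
"""Run the full pipeline in order: simulate -> VSI -> tendon lengths ->
morphospace -> calibration -> signal + ancestral states."""

import argparse
import subprocess
import sys
from pathlib import Path

HERE = Path(__file__).resolve().parent
STAGES = [
    ("01_simulate.py", ["--seed"]),
    ("02_vsi.py", []),
    ("03_tendon.py", []),
    ("04_morphospace.py", []),
    ("05_calibrate.py", []),
    ("06_signal_asr.py", ["--seed"]),
]


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    for script, extra in STAGES:
        cmd = [sys.executable, str(HERE / script)]
        if "--seed" in extra:
            cmd += ["--seed", str(args.seed)]
        print(f"== {script} ==", flush=True)
        subprocess.run(cmd, check=True)
        print(flush=True)


if __name__ == "__main__":
    main()
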