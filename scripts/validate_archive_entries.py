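#!/usr/bin/env python
"""Optional validation against archived EMDB/PDB entries (needs network).

Downloads deposited maps and models for a set of published entries, scores
each model against its map, and compares the recomputed model-average
Q-score to the archived value.  This is deliberately *not* part of the test
suite: the maps are hundreds of MB and require internet access.

Usage:
    python scripts/validate_table2.py [--entries EMD-7770 ...] [--workdir DIR]

Each entry downloads from the EMDB/RCSB public mirrors, so expect several
GB of traffic for the full set.
"""

from __future__ import annotations

import argparse
import gzip
import shutil
import urllib.request
from pathlib import Path

from qscore3d import QScoreParams, model_q, read_map, read_model

# (EMDB id, PDB id, reported resolution Å, archived model-average Q)
ENTRIES = [
    ("EMD-7770", "6cvm", 1.9, 0.70),
    ("EMD-22136", "6xdc", 2.9, 0.51),
    ("EMD-31385", "7ez0", 3.1, 0.43),
    ("EMD-23206", "7l6q", 7.0, 0.36),
    ("EMD-0449", "6nqd", 5.7, 0.001),
]

MAP_URL = "https://files.wwpdb.org/pub/emdb/structures/{emd}/map/{stem}.map.gz"
MODEL_URL = "https://files.rcsb.org/download/{pdb}.cif"


def fetch(url: str, dest: Path) -> Path:
    if not dest.exists():
        print(f"  downloading {url}")
        with urllib.request.urlopen(url) as resp, open(dest, "wb") as fh:
            shutil.copyfileobj(resp, fh)
    return dest


def gunzip(src: Path) -> Path:
    out = src.with_suffix("")
    if not out.exists():
        with gzip.open(src, "rb") as fin, open(out, "wb") as fout:
            shutil.copyfileobj(fin, fout)
    return out


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--entries", nargs="*", default=None,
                        help="EMDB ids to validate (default: all).")
    parser.add_argument("--workdir", type=Path, default=Path("scratch/archive_validation"))
    parser.add_argument("--seed", type=int, default=0)
    args = parser.parse_args()

    args.workdir.mkdir(parents=True, exist_ok=True)
    wanted = set(args.entries) if args.entries else None
    params = QScoreParams(rng_seed=args.seed)

    print(f"{'entry':<12}{'pdb':<8}{'d (Å)':<8}{'Q archived':<12}{'Q recomputed':<14}Δ")
    for emd, pdb, resolution, q_ref in ENTRIES:
        if wanted and emd not in wanted:
            continue
        stem = emd.replace("-", "_").lower()
        map_path = gunzip(fetch(MAP_URL.format(emd=emd, stem=stem),
                                args.workdir / f"{stem}.map.gz"))
        model_path = fetch(MODEL_URL.format(pdb=pdb), args.workdir / f"{pdb}.cif")
        grid = read_map(map_path)
        model = read_model(model_path)
        table = model_q(model, grid, params)
        q = table.model_average
        print(f"{emd:<12}{pdb:<8}{resolution:<8}{q_ref:<12}{q:<14.3f}{q - q_ref:+.3f}")


if __name__ == "__main__":
    main()
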