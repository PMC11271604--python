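#!/usr/bin/env python
"""Grid-box correlations between locally stored DBSI and histology maps.

Optional analysis script (not part of the test suite): given a directory of
co-registered map pairs, recompute the 2.5 mm grid-box Pearson correlations
between each histology density map and the matching fraction map.

Expected layout: for each specimen NAME, two files
    <dir>/NAME_histology.tif   (density map, float, percent)
    <dir>/NAME_dbsi.tif        (fraction map, float)
plus a JSON sidecar <dir>/NAME_meta.json with {"histology_cell_mm": x,
"dbsi_cell_mm": y}.

    python scripts/exvivo_correlations.py --data-dir maps/ --out corr.csv
"""

import argparse
import glob
import json
import os

import pandas as pd
import tifffile

from cdbsi.histology import grid_correlation


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data-dir", required=True)
    ap.add_argument("--box", type=float, default=2.5)
    ap.add_argument("--out", required=True)
    args = ap.parse_args()

    rows = []
    for hpath in sorted(glob.glob(os.path.join(args.data_dir,
                                               "*_histology.tif"))):
        name = os.path.basename(hpath)[: -len("_histology.tif")]
        dpath = os.path.join(args.data_dir, f"{name}_dbsi.tif")
        mpath = os.path.join(args.data_dir, f"{name}_meta.json")
        if not (os.path.exists(dpath) and os.path.exists(mpath)):
            print(f"skipping {name}: missing dbsi map or metadata")
            continue
        with open(mpath) as fh:
            meta = json.load(fh)
        hist = tifffile.imread(hpath).astype(float)
        dbsi = tifffile.imread(dpath).astype(float)
        r, p, n, _ = grid_correlation(
            (hist, meta["histology_cell_mm"]),
            (dbsi, meta["dbsi_cell_mm"]),
            box=args.box,
        )
        rows.append({"specimen": name, "r": r, "p": p, "n_boxes": n})
        print(f"{name}: r = {r:.3f}, p = {p:.2e}, n = {n}")

    if not rows:
        raise SystemExit("no map pairs found under --data-dir")
    pd.DataFrame(rows).to_csv(args.out, index=False)


if __name__ == "__main__":
    main()
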