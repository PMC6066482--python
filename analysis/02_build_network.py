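"""Build the FA-weighted reward network from the cohort voxel maps.

Streamline regions are estimated per group by a voxelwise one-sample t
(one-sided, p < 0.05 against zero); each subject's edge strength is the
mean FA over their group's region.  Writes the long-format edge-strength
table to results/network/.
"""

import argparse
from pathlib import Path

import numpy as np

from rewardnet import io
from rewardnet.atlas import default_atlas
from rewardnet.connectome import build_connectivity

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--alpha", type=float, default=0.05)
    ap.add_argument("--region-mode", choices=["group", "union"], default="group")
    args = ap.parse_args()

    atlas = default_atlas()
    subjects = io.read_subjects(ROOT / "results" / "cohort" / "subjects.tsv")
    voxel_data = io.read_voxel_npz(ROOT / "scratch" / "cohort_voxels.npz")
    records = build_connectivity(
        voxel_data, atlas, subjects["group"].to_dict(),
        alpha=args.alpha, region_mode=args.region_mode,
    )
    out = ROOT / "results" / "network" / "edge_strengths.tsv"
    io.write_edge_strengths(records, atlas, out, header=io.provenance_header())

    strengths = io.read_edge_strengths(out)
    print(f"connectivity matrices for {len(records)} subjects "
          f"({strengths.shape[1]} edges, region mode {args.region_mode})")
    for g in ("HA", "HC"):
        sel = subjects.index[subjects["group"] == g]
        print(f"  {g}: grand mean strength "
              f"{np.nanmean(strengths.loc[sel].to_numpy()):.4f}")
    print(f"edge strengths -> {out}")


if __name__ == "__main__":
    main()
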