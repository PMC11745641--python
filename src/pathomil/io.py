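"""On-disk interchange: outcome CSV, omics TSV, per-slide HDF5 feature bags.

Layout written by :func:`export_cohort` and read back by :func:`load_dataset`:

    out/
      outcomes.csv          sample_id, time_months, event, lnm
      omics.tsv             samples x features; header row names the features
      bags/<sample_id>.h5   datasets "features" (K x d), "coords" (K x 2);
                            attrs tile_size, magnification, encoder_id
"""

from __future__ import annotations

import os

import h5py
import numpy as np
import pandas as pd

from .types import FeatureBag, OmicsSchema, OmicsVector, Sample, SurvivalOutcome

__all__ = [
    "write_bag",
    "read_bag",
    "export_cohort",
    "load_dataset",
    "omics_feature_names",
]


def omics_feature_names(schema: OmicsSchema) -> list[str]:
    return (
        [f"mrna_{i:04d}" for i in range(schema.n_mrna)]
        + [f"mut_{i:02d}" for i in range(schema.n_mutations)]
        + [f"imm_{i:02d}" for i in range(schema.n_immune)]
        + [f"clin_{i:02d}" for i in range(schema.n_clinical)]
    )


def write_bag(bag: FeatureBag, path: str, tile_size: int = 256,
              magnification: str = "20x-equivalent") -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("features", data=bag.features)
        f.create_dataset("coords", data=bag.coords.astype(np.int64))
        f.attrs["tile_size"] = tile_size
        f.attrs["magnification"] = magnification
        f.attrs["encoder_id"] = bag.encoder_id
        f.attrs["sample_id"] = bag.sample_id


def read_bag(path: str) -> FeatureBag:
    with h5py.File(path, "r") as f:
        return FeatureBag(
            sample_id=str(f.attrs.get("sample_id", os.path.splitext(os.path.basename(path))[0])),
            features=f["features"][()],
            coords=f["coords"][()],
            encoder_id=str(f.attrs.get("encoder_id", "unknown")),
        )


def export_cohort(cohort, out_dir: str) -> None:
    """Write a SyntheticCohort (or any bag/omics/outcome triple list) to disk."""
    os.makedirs(os.path.join(out_dir, "bags"), exist_ok=True)
    ids = [b.sample_id for b in cohort.bags]
    pd.DataFrame(
        {
            "sample_id": ids,
            "time_months": [o.time_months for o in cohort.outcomes],
            "event": [o.event for o in cohort.outcomes],
            "lnm": [o.lnm for o in cohort.outcomes],
        }
    ).to_csv(os.path.join(out_dir, "outcomes.csv"), index=False)

    schema = cohort.omics[0].schema
    mat = np.stack([o.concatenated() for o in cohort.omics])
    pd.DataFrame(mat, index=pd.Index(ids, name="sample_id"),
                 columns=omics_feature_names(schema)).to_csv(
        os.path.join(out_dir, "omics.tsv"), sep="\t"
    )
    for bag in cohort.bags:
        write_bag(bag, os.path.join(out_dir, "bags", f"{bag.sample_id}.h5"))


def load_dataset(features_dir: str, omics_path: str, outcomes_path: str) -> list[Sample]:
    """Assemble Samples from a bag directory, an omics TSV and an outcomes CSV."""
    outcomes = pd.read_csv(outcomes_path).set_index("sample_id")
    omics = pd.read_csv(omics_path, sep="\t", index_col="sample_id")
    cols = omics.columns
    widths = {
        "mrna": int(cols.str.startswith("mrna_").sum()),
        "mutations": int(cols.str.startswith("mut_").sum()),
        "immune": int(cols.str.startswith("imm_").sum()),
        "clinical": int(cols.str.startswith("clin_").sum()),
    }
    samples = []
    for sample_id in outcomes.index:
        bag = read_bag(os.path.join(features_dir, f"{sample_id}.h5"))
        row = omics.loc[sample_id].to_numpy(dtype=float)
        start = 0
        blocks = {}
        for name in ("mrna", "mutations", "immune", "clinical"):
            blocks[name] = row[start : start + widths[name]]
            start += widths[name]
        out = outcomes.loc[sample_id]
        samples.append(
            Sample(
                bag=bag,
                omics=OmicsVector(**blocks),
                outcome=SurvivalOutcome(
                    time_months=float(out["time_months"]),
                    event=int(out["event"]),
                    lnm=float(out["lnm"]),
                ),
            )
        )
    return samples
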