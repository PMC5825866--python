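#!/usr/bin/env python
"""Generate the synthetic study inputs for both analysis arms.

Writes, under results/simulated/:
  * a 20-tissue x 5000-gene compendium with planted marker sets
    (compendium.tsv, compendium_expected.tsv, planted_markers.gmt),
  * two replicate query libraries (query.tsv): one biological realisation of
    a tissue under dataset-level noise (sd 0.5), sequenced twice under
    library-level noise (sd 0.1),
  * five-plane focal stacks for a four-dose micro-lens experiment
    (stacks/dose_<d>/lens_<i>/...), 15 lenses per dose, with planted
    per-lens transmittance and focus gain recorded in a manifest.
"""
import argparse
import dataclasses
import json
from pathlib import Path

import numpy as np

from microlens import CompendiumSimConfig, LensSimConfig
from microlens.io import write_expression_tsv, write_focal_stack, write_gmt
from microlens.simulate import simulate_compendium, simulate_focal_stack, simulate_query

DOSES_NG_ML = (0.0, 200.0, 500.0, 2000.0)
DOSE_TRANSMITTANCE = (0.95, 0.95, 0.85, 0.75)  # 500+ ng/ml lenses lose transparency
DOSE_FOCUS_GAIN = (1.0, 1.0, 0.5, 0.1)  # ...and fail to develop focusing
LENSES_PER_GROUP = 15
BETWEEN_LENS_SD = 0.02
BETWEEN_LENS_GAIN_SD = 0.05
QUERY_TISSUE = "tissue01"
DATASET_NOISE_SD = 0.5   # independent-measurement spread vs the compendium
LIBRARY_NOISE_SD = 0.1   # technical replicate-to-replicate spread


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--out-dir", type=Path, default=Path("results/simulated"))
    args = parser.parse_args()
    rng = np.random.default_rng(args.seed)
    out = args.out_dir
    out.mkdir(parents=True, exist_ok=True)

    # --- expression arm -------------------------------------------------
    cfg = CompendiumSimConfig(seed=int(rng.integers(0, 2**31 - 1)))
    sim = simulate_compendium(cfg)
    # one biological sample of the tissue, then two libraries of that sample
    sample = simulate_query(
        sim.expected, QUERY_TISSUE, noise_sd=DATASET_NOISE_SD,
        n_replicates=1, seed=int(rng.integers(0, 2**31 - 1)),
    )
    query = simulate_query(
        sample, str(sample.samples[0]), noise_sd=LIBRARY_NOISE_SD,
        n_replicates=cfg.n_query_replicates, seed=int(rng.integers(0, 2**31 - 1)),
    )
    write_expression_tsv(sim.matrix, out / "compendium.tsv")
    write_expression_tsv(sim.expected, out / "compendium_expected.tsv")
    write_expression_tsv(query, out / "query.tsv")
    write_gmt(sim.planted_markers, out / "planted_markers.gmt", description="planted")
    print(f"compendium: {cfg.n_tissues} tissues x {cfg.n_genes} genes, "
          f"{cfg.markers_per_tissue} markers/tissue at {cfg.marker_elevation:g}x, "
          f"lognormal noise sd {cfg.noise_sd}")
    print(f"query: {cfg.n_query_replicates} replicates of {QUERY_TISSUE}")

    # --- optics arm ------------------------------------------------------
    manifest = []
    for dose, planted_t, planted_g in zip(DOSES_NG_ML, DOSE_TRANSMITTANCE, DOSE_FOCUS_GAIN):
        for i in range(1, LENSES_PER_GROUP + 1):
            t_lens = float(np.clip(rng.normal(planted_t, BETWEEN_LENS_SD), 0, 1))
            g_lens = float(max(rng.normal(planted_g, BETWEEN_LENS_GAIN_SD), 0))
            lens_cfg = dataclasses.replace(
                LensSimConfig(), transmittance=t_lens, focus_gain=g_lens,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            stack_dir = out / "stacks" / f"dose_{dose:g}" / f"lens_{i:02d}"
            sidecar = write_focal_stack(simulate_focal_stack(lens_cfg), stack_dir, stem="lens")
            manifest.append({"dose_ng_ml": dose, "lens": i,
                             "planted_transmittance": t_lens,
                             "planted_focus_gain": g_lens,
                             "sidecar": str(sidecar.relative_to(out))})
    with open(out / "stack_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
        fh.write("\n")
    print(f"focal stacks: {len(manifest)} lenses across doses {DOSES_NG_ML} ng/ml, "
          f"planted transmittance {DOSE_TRANSMITTANCE}, focus gain {DOSE_FOCUS_GAIN}")


if __name__ == "__main__":
    main()
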