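#!/usr/bin/env python
"""Spatial association of liana- and epiphyte-hosting trees.

Ring cross-K curves on the mapped block with covariate-adjusted
random-labeling envelopes (10,000 reshuffles), one analysis per
reshuffled guild, mirroring the two panels of the field study.
"""

import warnings
from pathlib import Path

from cooccur.io import load_dataset_dir
from cooccur.spatial import MappedPattern, covariate_null_envelope, default_radii
from cooccur.viz import plot_envelope

ROOT = Path(__file__).resolve().parents[1] / "results"
N_SIM = 10000
SEED = 5


def main():
    ds = load_dataset_dir(ROOT / "data")
    pat = MappedPattern.from_dataset(ds, patch_id="Cedro")
    print(f"mapped block: {pat.n} trees, "
          f"{int(pat.marks['liana_host'].sum())} liana hosts, "
          f"{int(pat.marks['epi_host'].sum())} epiphyte hosts")
    radii = default_radii()
    radii = radii[radii <= 0.5 * min(*pat.side_lengths)]
    for label, frm, to in [
        ("epi_around_liana", "liana_host", "epi_host"),
        ("liana_around_epi", "epi_host", "liana_host"),
    ]:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            env = covariate_null_envelope(
                pat, frm, to, radii=radii, n_sim=N_SIM, seed=SEED
            )
        env.to_frame().to_csv(ROOT / f"spatial_{label}.csv", index=False)
        plot_envelope(env, ROOT / f"spatial_{label}.png", title=label)
        outside = env.radii[env.exceed != 0]
        msg = ", ".join(f"{r:g} m" for r in outside) if len(outside) else "none"
        print(f"{label}: radii outside the {100 * (1 - env.alpha):g}% envelope: {msg}")
    print("-> with the default generator the marks carry no extra spatial")
    print("   signal beyond dbh/species, so excursions should be rare.")


if __name__ == "__main__":
    main()
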