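"""Regenerate the packaged synthetic clock fixtures.

The packaged coefficient tables under ``src/dnamclocks/data/`` are
deterministic SYNTHETIC stand-ins for the published clock tables: placeholder
probe IDs and coefficients that carry the published *structure* — a 347-site
cortical clock whose site set overlaps the 353-site multi-tissue clock in 5
sites, the 514-site blood clock in 15 sites and the 513-site pheno-age clock
in 5 sites, with all other site sets disjoint.  Run from the repository root:

    python scripts/make_synthetic_clock_fixtures.py
"""

from pathlib import Path

import numpy as np

import sys

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from dnamclocks.age_transform import HORVATH, IDENTITY  # noqa: E402
from dnamclocks.core_io import ClockDefinition, write_clock_definition  # noqa: E402

OUT = Path(__file__).resolve().parents[1] / "src" / "dnamclocks" / "data"

N_CORTICAL, N_MULTI, N_BLOOD, N_PHENO = 347, 353, 514, 513
OVL_MULTI, OVL_BLOOD, OVL_PHENO = 5, 15, 5


def make_ids(rng: np.random.Generator, n: int, taken: set[str]) -> list[str]:
    ids: list[str] = []
    while len(ids) < n:
        cand = f"cg{rng.integers(0, 10**8):08d}"
        if cand not in taken:
            taken.add(cand)
            ids.append(cand)
    return ids


def build() -> None:
    rng = np.random.default_rng(20201201)
    taken: set[str] = set()

    cortical = make_ids(rng, N_CORTICAL, taken)
    # carve the published overlaps out of the cortical site set (disjoint chunks)
    shared_multi = cortical[:OVL_MULTI]
    shared_blood = cortical[OVL_MULTI:OVL_MULTI + OVL_BLOOD]
    shared_pheno = cortical[OVL_MULTI + OVL_BLOOD:OVL_MULTI + OVL_BLOOD + OVL_PHENO]

    multi = shared_multi + make_ids(rng, N_MULTI - OVL_MULTI, taken)
    blood = shared_blood + make_ids(rng, N_BLOOD - OVL_BLOOD, taken)
    pheno = shared_pheno + make_ids(rng, N_PHENO - OVL_PHENO, taken)

    def coefs(ids, scale):
        return dict(zip(ids, np.round(rng.normal(0.0, scale, len(ids)), 6)))

    def means(ids):
        return dict(zip(ids, np.round(rng.uniform(0.1, 0.9, len(ids)), 4)))

    clocks = [
        ClockDefinition("cortical_synthetic", 0.577682, coefs(cortical, 0.12),
                        means(cortical), transform=HORVATH),
        ClockDefinition("multi_tissue_synthetic", 0.695507, coefs(multi, 0.12),
                        means(multi), transform=HORVATH),
        ClockDefinition("blood_synthetic", 65.79295, coefs(blood, 4.0),
                        means(blood), transform=IDENTITY),
        ClockDefinition("pheno_age_synthetic", 60.664, coefs(pheno, 4.0),
                        means(pheno), transform=IDENTITY),
    ]
    names = ["cortical_clock", "multi_tissue_clock", "blood_clock", "pheno_age_clock"]
    OUT.mkdir(parents=True, exist_ok=True)
    for clock, stem in zip(clocks, names):
        path = OUT / f"{stem}.synthetic.tsv"
        write_clock_definition(clock, path)
        # prepend a provenance banner
        text = path.read_text()
        banner = ("# SYNTHETIC stand-in coefficient table (placeholder probe IDs and\n"
                  "# coefficients; site counts and cross-clock overlaps follow the\n"
                  "# published clock structure).  Regenerate with\n"
                  "# scripts/make_synthetic_clock_fixtures.py\n")
        path.write_text(banner + text)
        print(f"wrote {path} ({clock.n_sites} sites)")


if __name__ == "__main__":
    build()
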