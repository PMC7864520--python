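"""Full synthetic seeding assays: panel -> kinetics -> micrographs.

Emulates the wet-lab design the quantification stage expects: a panel of
AEF donor species crossed with a grid of AEF fractions, imaged at fixed
times in several independent replicates.  The AEF fraction (the relative
amount of seed extract mixed with the monomer) maps linearly onto the
kinetic model's seed fraction with a configurable ceiling; each replicate
gets its own kinetic observation noise and its own rendering seed, all
derived deterministically from one master seed.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .containers import Micrograph, MicrographMeta
from .kinetics import KineticParams, simulate_kinetics
from .render import ImagingParams, render_micrograph

__all__ = ["aef_to_seed_fraction", "generate_assay"]


def aef_to_seed_fraction(aef_fraction: float, ceiling: float = 0.1) -> float:
    """Linear map from relative AEF amount in [0,1] to initial seed mass."""
    if not 0.0 <= aef_fraction <= 1.0:
        raise ValueError("aef_fraction must lie in [0, 1]")
    if not 0.0 < ceiling <= 1.0:
        raise ValueError("ceiling must lie in (0, 1]")
    return aef_fraction * ceiling


def _image_seed(master: int, *key: int) -> int:
    return int(np.random.SeedSequence((master, *key)).generate_state(1)[0])


def generate_assay(
    species_kinetics: dict[str, KineticParams],
    species_imaging: dict[str, ImagingParams],
    aef_fractions,
    times_h,
    replicates: int = 3,
    seed_ceiling: float = 0.1,
    rng_seed: int = 0,
) -> list[Micrograph]:
    """Generate micrographs for every (species, fraction, time, replicate).

    ``species_kinetics[s].seed_fraction`` is ignored; the seed fraction is
    set per panel cell as ``aef_fraction * seed_ceiling``.  Returns
    ``len(species) * len(fractions) * len(times) * replicates`` images,
    in deterministic (species, fraction, replicate, time) order.
    """
    if set(species_kinetics) != set(species_imaging):
        raise ValueError("kinetic and imaging panels must list the same species")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    times = list(times_h)
    images: list[Micrograph] = []
    for si, species in enumerate(sorted(species_kinetics)):
        kin_base = species_kinetics[species]
        img_base = species_imaging[species]
        for fi, aef in enumerate(aef_fractions):
            kin = replace(kin_base,
                          seed_fraction=aef_to_seed_fraction(aef, seed_ceiling))
            for rep in range(replicates):
                rng = np.random.default_rng((rng_seed, si, fi, rep))
                fractions = simulate_kinetics(kin, times, rng=rng)
                for ti, (t, mass) in enumerate(zip(times, fractions)):
                    p = replace(img_base,
                                rng_seed=_image_seed(rng_seed, si, fi, rep, ti))
                    meta = MicrographMeta(species=species, aef_fraction=aef,
                                          time_h=float(t), replicate_id=rep)
                    images.append(render_micrograph(float(mass), p, meta))
    return images
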