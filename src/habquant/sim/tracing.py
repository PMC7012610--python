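"""Multi-animal rabies-tracing datasets with configured marker proportions.

Each retrogradely labeled (RbV-N+) neuron is assigned at most one subtype
marker by a multinomial draw over the configured proportions (the
remainder is unlabeled). The dataset is returned either as per-animal
coverage tables (fast path, bypassing imaging) or as per-animal synthetic
FISH images to exercise the full quantification pipeline.

The default presets mirror LHb input tracing from VTA GABAergic
(VGAT-Cre: lateral/oval-medial dominated) and dopaminergic (DAT-Cre:
oval/medial dominated) starter populations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .counts import ConfigurationError
from .fish import FishGroundTruth, FishSimConfig, generate_fish_image

#: Marker proportions among RbV-N+ LHb cells, VTA GABAergic starters.
VGAT_PRESET = {"Gpr151": 0.48, "Chrm3": 0.41, "Vgf": 0.10, "Sst": 0.02}
#: Marker proportions among RbV-N+ LHb cells, VTA dopaminergic starters.
DAT_PRESET = {"Chrm3": 0.61, "Vgf": 0.20, "Gpr151": 0.10, "Sst": 0.007}

#: (coverage fraction, intensity) defaults for a marker-positive cell, the
#: RbV-N channel of every labeled cell, and residual off-channel signal.
_POSITIVE_PROFILE = (0.45, 140.0)
_RBV_PROFILE = (0.55, 140.0)
_OFF_PROFILE = (0.004, 90.0)


@dataclass
class TracingAnimal:
    """One animal's simulated tracing data."""

    animal_id: str
    coverage: pd.DataFrame  # per-cell, per-channel coverage % (0-100)
    truth_markers: np.ndarray  # assigned marker name or "" per cell
    image: np.ndarray | None = None  # channels x rows x cols when simulated
    channels: list[str] | None = None
    truth: FishGroundTruth | None = None


def _assign_markers(n_cells, marker_names, probs, rng):
    cats = list(marker_names) + [""]
    p = np.concatenate([probs, [max(0.0, 1.0 - probs.sum())]])
    p = p / p.sum()
    return np.array(cats, dtype=object)[rng.choice(len(cats), size=n_cells, p=p)]


def generate_tracing_dataset(
    n_animals: int,
    cells_per_animal: int,
    marker_proportions: dict | None = None,
    coverage_profiles: dict | None = None,
    seed: int = 0,
    mode: str = "coverage",
    image_shape: tuple[int, int] = (640, 640),
) -> list[TracingAnimal]:
    """Simulate RbV-N+ cells for ``n_animals`` animals.

    Parameters
    ----------
    marker_proportions
        Marker name -> fraction of RbV-N+ cells positive for it; must sum
        to at most 1 (remainder unlabeled). Defaults to the VGAT preset.
    coverage_profiles
        Optional ``{"positive": (cov, intensity), "rbv": ..., "off": ...}``
        overrides for channel signal strength.
    mode
        ``"coverage"`` emits coverage tables directly; ``"images"`` renders
        one synthetic FISH image per animal (slower, full-pipeline input).
    """
    if marker_proportions is None:
        marker_proportions = dict(VGAT_PRESET)
    marker_names = list(marker_proportions)
    probs = np.array([marker_proportions[m] for m in marker_names], dtype=float)
    if (probs < 0).any() or probs.sum() > 1.05:
        raise ConfigurationError("marker proportions must be >= 0 and sum to <= 1")
    # published rounded percentages can overshoot 1 slightly (e.g. 101%);
    # renormalize those, keep any genuine remainder as unlabeled cells
    if probs.sum() > 1.0:
        probs = probs / probs.sum()
    probs = np.clip(probs, 0, None)

    prof = {"positive": _POSITIVE_PROFILE, "rbv": _RBV_PROFILE, "off": _OFF_PROFILE}
    if coverage_profiles:
        prof.update(coverage_profiles)

    rng = np.random.default_rng(seed)
    channels = ["RbV-N"] + marker_names
    animals: list[TracingAnimal] = []
    for ai in range(n_animals):
        animal_id = f"M{ai + 1}"
        arng = np.random.default_rng(rng.integers(2**31))
        if mode == "coverage":
            markers = _assign_markers(cells_per_animal, marker_names, probs, arng)
            cov = pd.DataFrame(
                0.0,
                index=pd.RangeIndex(1, cells_per_animal + 1, name="cell"),
                columns=channels,
            )
            cov["RbV-N"] = 100 * np.clip(
                arng.normal(prof["rbv"][0], 0.08, size=cells_per_animal), 0.05, 0.95
            )
            for m in marker_names:
                pos = markers == m
                cov.loc[:, m] = 100 * arng.uniform(0.0, 0.015, size=cells_per_animal)
                cov.loc[pos.nonzero()[0] + 1, m] = 100 * np.clip(
                    arng.normal(prof["positive"][0], 0.1, size=int(pos.sum())),
                    0.08,
                    0.95,
                )
            animals.append(TracingAnimal(animal_id, cov, markers))
        elif mode == "images":
            # subtype = assigned marker (or "unlabeled"); every cell is RbV-N+
            subtype_props = {m: float(p) for m, p in zip(marker_names, probs)}
            rest = 1.0 - probs.sum()
            if rest > 1e-12:
                subtype_props["unlabeled"] = rest
            channel_profiles = {}
            for st in subtype_props:
                chp = {"RbV-N": prof["rbv"]}
                for m in marker_names:
                    chp[m] = prof["positive"] if m == st else prof["off"]
                channel_profiles[st] = chp
            fc = FishSimConfig(
                image_shape=image_shape,
                n_cells=cells_per_animal,
                subtype_proportions=subtype_props,
                channel_profiles=channel_profiles,
                seed=int(arng.integers(2**31)),
            )
            image, chs, truth = generate_fish_image(fc)
            markers = np.where(
                np.isin(truth.subtypes, marker_names), truth.subtypes, ""
            ).astype(object)
            cov = truth.coverage * 100.0
            animals.append(
                TracingAnimal(animal_id, cov, markers, image, chs, truth)
            )
        else:
            raise ValueError(f"unknown mode {mode!r}")
    return animals
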