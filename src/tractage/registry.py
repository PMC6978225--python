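"""Canonical tract and diffusion-index registries.

Every array in the package is ordered by these registries: 76 white matter
tract bundles along the first axis, 100 normalized steps along the second,
and 7 diffusion indices along the third.  Feature vectors flatten the
(tract, index) grid tract-major, index-minor, giving 76 x 7 = 532 features.

The 76-tract name list is a synthetic reconstruction: the underlying atlas
enumerates bilateral association fibers, frontostriatal and thalamic
projection systems, and segmented callosal fibers, but no public table
prints all 76 labels.  The names below follow the published abbreviation
conventions (e.g. "UF_R", "FS_OFC_R", "CF_genu") and are fixed as the
package's canonical ordering.
"""

from __future__ import annotations

# Bilateral bundles (one _L and one _R entry each): association fibers,
# limbic fibers, frontostriatal (FS) and thalamic-radiation (TR) projection
# systems, and other major projection/visual pathways.
_BILATERAL = (
    "AF",            # arcuate fasciculus
    "UF",            # uncinate fasciculus
    "IFOF",          # inferior fronto-occipital fasciculus
    "ILF",           # inferior longitudinal fasciculus
    "SLF_I",         # superior longitudinal fasciculus, dorsal branch
    "SLF_II",
    "SLF_III",
    "PerpF",         # perpendicular fasciculus
    "MdLF",          # middle longitudinal fasciculus
    "EmC",           # extreme capsule
    "FAT",           # frontal aslant tract
    "VOF",           # vertical occipital fasciculus
    "CG_C",          # cingulum, cingulate portion
    "CG_H",          # cingulum, parahippocampal portion
    "FX",            # fornix
    "ST",            # stria terminalis
    "FS_OFC",        # frontostriatal tract, orbitofrontal cortex
    "FS_DLPFC",      # frontostriatal tract, dorsolateral prefrontal cortex
    "FS_VLPFC",      # frontostriatal tract, ventrolateral prefrontal cortex
    "FS_MotorPC",    # frontostriatal tract, motor precentral gyrus
    "TR_anterior",   # thalamic radiation, anterior part
    "TR_dorsal",     # thalamic radiation, dorsal part
    "TR_superior",   # thalamic radiation, superior part
    "TR_posterior",  # thalamic radiation, posterior part
    "TR_OFC",        # thalamic radiation, orbitofrontal part
    "CST",           # corticospinal tract
    "CPT_frontal",   # corticopontine tract, frontal part
    "CPT_parietal",  # corticopontine tract, parietal part
    "AR",            # acoustic radiation
    "OR",            # optic radiation
)

# Callosal fiber (CF) segments, genu to splenium plus cortical targets.
_CALLOSAL = (
    "CF_rostrum",
    "CF_genu",
    "CF_OFC",
    "CF_DLPFC",
    "CF_body_prefrontal",
    "CF_body_premotor",
    "CF_body_precentral",
    "CF_body_postcentral",
    "CF_body_parietal",
    "CF_isthmus",
    "CF_splenium",
    "CF_tapetum",
    "CF_temporal",
    "CF_occipital",
    "CF_precuneus",
    "CF_hippocampal",
)

TRACT_NAMES: tuple[str, ...] = tuple(
    f"{name}_{side}" for name in _BILATERAL for side in ("L", "R")
) + _CALLOSAL

INDEX_NAMES: tuple[str, ...] = ("GFA", "AD", "RD", "MD", "NG", "NGO", "NGP")

N_TRACTS = len(TRACT_NAMES)
N_STEPS = 100
N_INDICES = len(INDEX_NAMES)
N_FEATURES = N_TRACTS * N_INDICES

assert N_TRACTS == 76 and N_FEATURES == 532

TRACT_TO_IDX = {name: i for i, name in enumerate(TRACT_NAMES)}
INDEX_TO_IDX = {name: i for i, name in enumerate(INDEX_NAMES)}


def feature_names() -> list[str]:
    """532 feature labels, tract-major / index-minor (``"UF_R:RD"``)."""
    return [f"{t}:{k}" for t in TRACT_NAMES for k in INDEX_NAMES]


def feature_index(tract: str, index: str) -> int:
    """Position of a (tract, index) cell in the flat 532-feature order."""
    return TRACT_TO_IDX[tract] * N_INDICES + INDEX_TO_IDX[index]
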