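"""Default node parcellation.

The default graph nodes are the 90 cerebral regions of the Automated
Anatomical Labeling (AAL) atlas plus one node per cerebellar hemisphere,
giving 92 regions.  Only the label strings matter to this package — all
computation is purely on the region-averaged signals — but keeping the
canonical names lets node sets for hypotheses ("bilateral thalami") and
specificity checks ("bilateral cerebella", "bilateral primary motor
cortices") be expressed the way the field writes them.
"""

from __future__ import annotations

_AAL_STEMS = [
    "Precentral", "Frontal_Sup", "Frontal_Sup_Orb", "Frontal_Mid",
    "Frontal_Mid_Orb", "Frontal_Inf_Oper", "Frontal_Inf_Tri",
    "Frontal_Inf_Orb", "Rolandic_Oper", "Supp_Motor_Area", "Olfactory",
    "Frontal_Sup_Medial", "Frontal_Med_Orb", "Rectus", "Insula",
    "Cingulum_Ant", "Cingulum_Mid", "Cingulum_Post", "Hippocampus",
    "ParaHippocampal", "Amygdala", "Calcarine", "Cuneus", "Lingual",
    "Occipital_Sup", "Occipital_Mid", "Occipital_Inf", "Fusiform",
    "Postcentral", "Parietal_Sup", "Parietal_Inf", "SupraMarginal",
    "Angular", "Precuneus", "Paracentral_Lobule", "Caudate", "Putamen",
    "Pallidum", "Thalamus", "Heschl", "Temporal_Sup", "Temporal_Pole_Sup",
    "Temporal_Mid", "Temporal_Pole_Mid", "Temporal_Inf",
]

#: 92 region labels: 45 bilateral AAL cerebral pairs + bilateral cerebellum.
DEFAULT_LABELS: list[str] = [
    f"{stem}_{side}" for stem in _AAL_STEMS for side in ("L", "R")
] + ["Cerebellum_L", "Cerebellum_R"]

#: A priori hypothesis nodes (thalamic hubs of the tremor circuit).
THALAMUS_NODES = ["Thalamus_L", "Thalamus_R"]

#: Nodal-specificity control nodes within the cerebello-thalamo-cortical loop.
CEREBELLUM_NODES = ["Cerebellum_L", "Cerebellum_R"]
MOTOR_CORTEX_NODES = ["Precentral_L", "Precentral_R"]

#: Seed regions for the seed-connectivity stage (bilateral pairs).
PUTAMEN_NODES = ["Putamen_L", "Putamen_R"]
PALLIDUM_NODES = ["Pallidum_L", "Pallidum_R"]


def label_indices(labels: list[str], query: list[str]) -> list[int]:
    """Map region names to positional indices, failing on unknown names."""
    missing = [q for q in query if q not in labels]
    if missing:
        raise KeyError(f"unknown node label(s): {missing}")
    pos = {lab: i for i, lab in enumerate(labels)}
    return [pos[q] for q in query]
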