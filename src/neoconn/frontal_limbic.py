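"""Worked example: a published-style frontal-limbic subnetwork.

A reference subnetwork of 20 frontal, cingulate and limbic regions of the
neonatal AAL-style parcellation sharing 25 edges, in which reduced
neonatal connectivity tracks higher toddler externalizing scores.  Each
node carries its core/periphery membership from the group-level
decomposition (6 core, 14 peripheral) and each edge its GLM t-statistic
at the primary threshold t = 3.1.  The table is used as a ground-truth
fixture for core/feeder/peripheral edge classification: applying the
endpoint rule to the node labels must reproduce the recorded edge types
(2 core, 10 feeder, 13 peripheral).

Region naming follows the source parcellation; "Inferior frontal gyrus
(Opercular)" and "Inferior frontal gyrus (pars opercularis)" are the same
region and are normalized to the latter spelling.
"""

from __future__ import annotations

import pandas as pd

from .io import Edge

__all__ = [
    "subnetwork_nodes",
    "subnetwork_edges",
    "subnetwork_edge_list",
    "node_labels",
]

# (region, core/periphery membership)
_NODES = [
    ("Superior frontal gyrus (medial) left", "core"),
    ("Superior frontal gyrus (medial) right", "core"),
    ("Superior frontal gyrus (dorsal) left", "core"),
    ("Superior frontal gyrus (dorsal) right", "core"),
    ("Middle frontal gyrus left", "core"),
    ("Middle frontal gyrus right", "core"),
    ("Rectus gyrus left", "periphery"),
    ("Orbitofrontal cortex (medial) left", "periphery"),
    ("Orbitofrontal cortex (medial) right", "periphery"),
    ("Orbitofrontal cortex (middle) left", "periphery"),
    ("Orbitofrontal cortex (middle) right", "periphery"),
    ("Orbitofrontal cortex (superior) left", "periphery"),
    ("Orbitofrontal cortex (superior) right", "periphery"),
    ("Inferior frontal gyrus (pars opercularis) left", "periphery"),
    ("Inferior frontal gyrus (pars opercularis) right", "periphery"),
    ("Inferior frontal gyrus (pars triangularis) right", "periphery"),
    ("Supplementary motor area left", "periphery"),
    ("Posterior cingulate gyrus right", "periphery"),
    ("Hippocampus right", "periphery"),
    ("Amygdala right", "periphery"),
]

# (node_a, node_b, recorded edge type, t-statistic of the negative contrast)
_EDGES = [
    ("Inferior frontal gyrus (pars opercularis) right",
     "Superior frontal gyrus (medial) left", "feeder", 5.02),
    ("Inferior frontal gyrus (pars opercularis) right",
     "Superior frontal gyrus (dorsal) left", "feeder", 4.08),
    ("Orbitofrontal cortex (medial) left",
     "Orbitofrontal cortex (medial) right", "peripheral", 3.7),
    ("Inferior frontal gyrus (pars opercularis) right",
     "Inferior frontal gyrus (pars opercularis) left", "peripheral", 3.69),
    ("Superior frontal gyrus (medial) right",
     "Orbitofrontal cortex (medial) left", "feeder", 3.65),
    ("Inferior frontal gyrus (pars opercularis) right",
     "Supplementary motor area left", "peripheral", 3.65),
    ("Orbitofrontal cortex (medial) right",
     "Rectus gyrus left", "peripheral", 3.64),
    ("Inferior frontal gyrus (pars triangularis) right",
     "Superior frontal gyrus (medial) left", "feeder", 3.55),
    ("Middle frontal gyrus right",
     "Superior frontal gyrus (medial) left", "core", 3.52),
    ("Superior frontal gyrus (medial) left",
     "Orbitofrontal cortex (medial) right", "feeder", 3.47),
    ("Orbitofrontal cortex (middle) right",
     "Posterior cingulate gyrus right", "peripheral", 3.36),
    ("Orbitofrontal cortex (middle) right",
     "Orbitofrontal cortex (medial) left", "peripheral", 3.34),
    ("Superior frontal gyrus (medial) left",
     "Superior frontal gyrus (medial) right", "core", 3.32),
    ("Inferior frontal gyrus (pars opercularis) right",
     "Middle frontal gyrus left", "feeder", 3.3),
    ("Inferior frontal gyrus (pars opercularis) right",
     "Orbitofrontal cortex (middle) left", "peripheral", 3.26),
    ("Orbitofrontal cortex (superior) left",
     "Orbitofrontal cortex (medial) right", "peripheral", 3.23),
    ("Orbitofrontal cortex (medial) left",
     "Hippocampus right", "peripheral", 3.23),
    ("Inferior frontal gyrus (pars opercularis) right",
     "Orbitofrontal cortex (medial) left", "peripheral", 3.2),
    ("Orbitofrontal cortex (superior) right",
     "Superior frontal gyrus (medial) left", "feeder", 3.19),
    ("Orbitofrontal cortex (superior) left",
     "Amygdala right", "peripheral", 3.16),
    ("Orbitofrontal cortex (superior) left",
     "Superior frontal gyrus (medial) right", "feeder", 3.16),
    ("Superior frontal gyrus (dorsal) right",
     "Orbitofrontal cortex (medial) left", "feeder", 3.15),
    ("Orbitofrontal cortex (superior) right",
     "Orbitofrontal cortex (medial) left", "peripheral", 3.13),
    ("Inferior frontal gyrus (pars opercularis) right",
     "Orbitofrontal cortex (superior) left", "peripheral", 3.13),
    ("Middle frontal gyrus left",
     "Orbitofrontal cortex (medial) right", "feeder", 3.11),
]


def subnetwork_nodes() -> pd.DataFrame:
    """The 20 subnetwork regions with their core/periphery membership."""
    return pd.DataFrame(_NODES, columns=["region", "partition_label"])


def subnetwork_edges() -> pd.DataFrame:
    """The 25 subnetwork edges with recorded type and t-statistic."""
    return pd.DataFrame(_EDGES, columns=["node_a", "node_b", "type", "t"])


def subnetwork_edge_list() -> list:
    """The 25 edges as :class:`~neoconn.io.Edge` objects (t as the weight)."""
    return [Edge(a, b, t) for a, b, _, t in _EDGES]


def node_labels() -> dict:
    """region -> core/periphery mapping for the 20 subnetwork nodes."""
    return dict(_NODES)
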