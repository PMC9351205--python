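"""Node roles of the 10-node lung graph and the canonical ordering used everywhere.

Canonical order: airway landmarks first (root, carina/"center", distal left
and right main bronchi), then the five lobes superior-to-inferior and
left-to-right, then the tumor node.  Feature matrices, neighbor sequences
and serialized graphs all follow this order.
"""

from __future__ import annotations

import enum


class NodeRole(str, enum.Enum):
    """Role tag of a lung-graph node."""

    ROOT = "ROOT"
    CENTER = "CENTER"
    LEFT = "LEFT"
    RIGHT = "RIGHT"
    LUL = "LUL"
    LLL = "LLL"
    RUL = "RUL"
    RML = "RML"
    RLL = "RLL"
    TUMOR = "TUMOR"


CANONICAL_ROLE_ORDER: tuple[NodeRole, ...] = (
    NodeRole.ROOT,
    NodeRole.CENTER,
    NodeRole.LEFT,
    NodeRole.RIGHT,
    NodeRole.LUL,
    NodeRole.LLL,
    NodeRole.RUL,
    NodeRole.RML,
    NodeRole.RLL,
    NodeRole.TUMOR,
)

#: Lobe roles in label-map order: label i+1 in a lobe label volume is LOBE_ROLES[i].
LOBE_ROLES: tuple[NodeRole, ...] = (
    NodeRole.LUL,
    NodeRole.LLL,
    NodeRole.RUL,
    NodeRole.RML,
    NodeRole.RLL,
)

#: Lobe label value (1..5) keyed by role.
LOBE_LABELS: dict[NodeRole, int] = {role: i + 1 for i, role in enumerate(LOBE_ROLES)}

ROLE_INDEX: dict[NodeRole, int] = {r: i for i, r in enumerate(CANONICAL_ROLE_ORDER)}
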