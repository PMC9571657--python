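import pytest

from cannasym.fixtures import load_collections
from cannasym.topology import BractPlacement, FlorescenceNode, assign_ids


@pytest.fixture(scope="session")
def builtin_records():
    return load_collections("builtin")


@pytest.fixture(scope="session")
def aberrant_records(builtin_records):
    return [r for r in builtin_records if not r.normal]


@pytest.fixture(scope="session")
def by_id(builtin_records):
    return {r.id: r for r in builtin_records}


def make_tree(branch_angles, lateral=True, statuses=None):
    """A one-flower tree with given proceeding-order bract angles.

    The focal flower has id "0"; when *lateral* it carries a primary bract
    (abaxial), otherwise it terminates the axis.
    """
    statuses = statuses or ["mature"] * len(branch_angles)
    f1 = FlorescenceNode(
        kind="flower",
        order=1,
        subtending_bract=BractPlacement(order_index=1, angle_deg=180.0) if lateral else None,
        children=[
            FlorescenceNode(
                kind="flower",
                order=2,
                subtending_bract=BractPlacement(order_index=2, angle_deg=a),
                status=s,
            )
            for a, s in zip(branch_angles, statuses)
        ],
    )
    return assign_ids(FlorescenceNode(kind="axis", order=0, children=[f1]))
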