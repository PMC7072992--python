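import io

import pytest
from skbio import TreeNode

from riboprot.catalog import load_tilapia_catalog


@pytest.fixture(scope="session")
def tilapia():
    """The packaged 92-gene Nile tilapia RP catalog."""
    return load_tilapia_catalog()


def newick(s: str) -> TreeNode:
    return TreeNode.read(io.StringIO(s), convert_underscores=False)
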