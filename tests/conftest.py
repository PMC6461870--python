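import dendropy
import pytest

from sporetrade.synthetic_data import SimulationConfig, make_fixture_trait_table


@pytest.fixture()
def trait_csv(tmp_path):
    """Seeded 10-row spore-trait CSV with globose, subglobose, dimorphic rows."""
    path = tmp_path / "traits.csv"
    make_fixture_trait_table(path, SimulationConfig(seed=7))
    return path


@pytest.fixture()
def balanced_tree():
    """Four-tip balanced ultrametric tree, unit branch lengths."""
    return dendropy.Tree.get(
        data="((a:1,b:1):1,(c:1,d:1):1);", schema="newick",
        preserve_underscores=True)


def star_tree(n: int, length: float = 1.0) -> dendropy.Tree:
    tips = ",".join(f"t{i}:{length}" for i in range(n))
    return dendropy.Tree.get(data=f"({tips});", schema="newick",
                             preserve_underscores=True)
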