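import numpy as np
import pytest

from dietshift import CountMatrix, GuildMap, Survey, study_like_fixture


@pytest.fixture()
def surveys_pair():
    return [
        Survey(id="2004", year=2004, pellet_count=535),
        Survey(id="2012", year=2012, pellet_count=159),
    ]


@pytest.fixture()
def small_counts():
    """3 taxa × 2 surveys with one unexploited category per survey."""
    return CountMatrix(
        ["Murinae", "Soricinae", "Crocidurinae"],
        ["2004", "2012"],
        np.array([[10, 5], [2, 0], [0, 3]]),
    )


@pytest.fixture()
def demo_dataset():
    return study_like_fixture(seed=0)


def write_csv(path, header, rows):
    lines = [header] + [",".join(str(x) for x in r) for r in rows]
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path
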