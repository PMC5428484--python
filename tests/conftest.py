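import pandas as pd
import pytest

from gofunsim.corpus import AnnotationCorpus, build_ic, parse_gaf
from gofunsim.fixtures import FixtureSpec, make_world
from gofunsim.ontology_io import parse_obo

CHAIN_OBO = """format-version: 1.2
ontology: go-test

[Term]
id: GO:0000001
name: root
namespace: biological_process

[Term]
id: GO:0000002
name: A
namespace: biological_process
is_a: GO:0000001

[Term]
id: GO:0000003
name: B
namespace: biological_process
is_a: GO:0000002
"""


@pytest.fixture
def chain_dag(tmp_path):
    """root <- A <- B chain in BP."""
    p = tmp_path / "chain.obo"
    p.write_text(CHAIN_OBO)
    return parse_obo(p)["BP"]


@pytest.fixture(scope="session")
def world(tmp_path_factory):
    """Default synthetic two-organism world, parsed once per session."""
    outdir = tmp_path_factory.mktemp("world")
    return make_world(FixtureSpec(seed=11), outdir)


@pytest.fixture(scope="session")
def dags(world):
    return parse_obo(world.obo_path)


@pytest.fixture(scope="session")
def corpus(world, dags):
    frames = [parse_gaf(p, dags).records for p in world.gaf_paths.values()]
    return AnnotationCorpus(records=pd.concat(frames, ignore_index=True))


@pytest.fixture(scope="session")
def ics(corpus, dags):
    return {ns: build_ic(corpus, dags[ns]) for ns in dags}


def brute_force_ancestors(dag, term):
    """Independent oracle: reflexive ancestor closure by explicit DFS
    over the parent lists stored on the Term objects."""
    seen = set()
    stack = [dag.resolve(term)]
    while stack:
        t = stack.pop()
        if t in seen:
            continue
        seen.add(t)
        stack.extend(p for p, _ in dag.terms[t].parents)
    return frozenset(seen)
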