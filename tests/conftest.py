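import io
import textwrap

import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")

from ltrfam.model import Project
from ltrfam.pipeline import project_from_simulation
from ltrfam.simulate import FamilySpec, simulate

TWO_CANDIDATE_GFF3 = textwrap.dedent(
    """\
    ##gff-version 3
    seq0\ttest\tLTR_retrotransposon\t101\t1100\t.\t+\t.\tID=cand1
    seq0\ttest\tlong_terminal_repeat\t101\t250\t.\t+\t.\tParent=cand1
    seq0\ttest\tprimer_binding_site\t251\t262\t.\t+\t.\tParent=cand1
    seq0\ttest\tprotein_match\t400\t700\t.\t+\t.\tParent=cand1;name=RVT_1
    seq0\ttest\tRR_tract\t930\t950\t.\t+\t.\tParent=cand1
    seq0\ttest\tlong_terminal_repeat\t951\t1100\t.\t+\t.\tParent=cand1
    seq0\ttest\tLTR_retrotransposon\t2001\t3000\t.\t-\t.\tID=cand2
    seq0\ttest\tlong_terminal_repeat\t2001\t2150\t.\t-\t.\tParent=cand2
    seq0\ttest\tlong_terminal_repeat\t2851\t3000\t.\t-\t.\tParent=cand2
    """
)


@pytest.fixture
def two_candidate_gff3():
    return io.StringIO(TWO_CANDIDATE_GFF3)


@pytest.fixture
def demo_specs():
    return [
        FamilySpec(name="famA", n_copies=4, superfamily="COPIA", mutation_rate=0.005),
        FamilySpec(name="famB", n_copies=4, superfamily="GYPSY", mutation_rate=0.005),
    ]


@pytest.fixture
def sim_project(demo_specs) -> Project:
    result = simulate(demo_specs, genome_len=60_000, seed=11)
    project = project_from_simulation(result)
    project._truth = result.truth  # convenience for tests
    return project
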