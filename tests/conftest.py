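import io
import textwrap

import pytest

from clinannot.fixtures import FixtureSpec, generate_fixture_set
from clinannot.ontology import XrefIndex, load_ontology
from clinannot.pipeline import RunConfig, run_annotation

MS_OBO = textwrap.dedent(
    """\
    format-version: 1.4
    ontology: test-efo

    [Term]
    id: EFO:0003929
    name: Relapsing remitting multiple sclerosis
    xref: MedGen:C0751967

    [Term]
    id: EFO:0003885
    name: multiple sclerosis
    synonym: "MS" EXACT []
    synonym: "disseminated sclerosis" RELATED []

    [Term]
    id: MONDO:0005301
    name: multiple sclerosis (MONDO)
    synonym: "multiple sclerosis" EXACT []

    [Term]
    id: EFO:0000001
    name: old multiple sclerosis term
    is_obsolete: true
    replaced_by: EFO:0003885

    [Term]
    id: EFO:0000002
    name: dead end term
    is_obsolete: true
    """
)


@pytest.fixture(scope="session")
def ms_store():
    return load_ontology(io.StringIO(MS_OBO))


@pytest.fixture(scope="session")
def ms_xrefs():
    index = XrefIndex()
    index.add("MedGen", "C0751967", "EFO:0003929")
    index.add("MedGen", "C7000001", "MONDO:0005301")
    index.add("MONDO", "0005301", "EFO:0003885")
    return index


@pytest.fixture(scope="session")
def fixture_set(tmp_path_factory):
    """Standard toy release: 40 records, seed 1, demo record included."""
    out = tmp_path_factory.mktemp("fixture")
    return generate_fixture_set(FixtureSpec(seed=1, n_records=40), out)


def make_run_config(fx, out_path, **overrides) -> RunConfig:
    cfg = RunConfig(
        release_xml=str(fx.release_xml),
        ontology=str(fx.ontology),
        xref_table=str(fx.xref_table),
        repository=str(fx.repository),
        gff3=str(fx.genes_gff3),
        fasta=str(fx.genome_fasta),
        accession_map=str(fx.accession_map),
        output=str(out_path),
    )
    for key, value in overrides.items():
        setattr(cfg, key, value)
    return cfg


@pytest.fixture(scope="session")
def run_result(fixture_set, tmp_path_factory):
    out = tmp_path_factory.mktemp("run") / "annotated.xml"
    return run_annotation(make_run_config(fixture_set, out))
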