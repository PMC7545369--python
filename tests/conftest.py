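import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, max_examples=50)
settings.load_profile("deterministic")

from moltnet import pipeline, synthdata
from moltnet.reconstruct import NetworkReaction, Reconstruction


@pytest.fixture(scope="session")
def db():
    return synthdata.make_refdb(seed=1)


@pytest.fixture(scope="session")
def pipeline_result():
    return pipeline.run_pipeline(seed=1)


def make_reaction(rid, stoich, reversible=True, category="metabolic",
                  pathway="00010", subsystem="Carbohydrate metabolism",
                  gpr=(), main=None):
    return NetworkReaction(
        id=rid, stoichiometry=dict(stoich),
        main_stoichiometry=dict(main if main is not None else stoich),
        reversible=reversible, category=category, gpr=gpr,
        pathway_id=pathway, subsystem=subsystem)


def make_recon(*reactions, provenance="draft"):
    recon = Reconstruction()
    for rxn in reactions:
        recon.add_reaction(rxn, provenance=provenance)
    return recon


@pytest.fixture
def chain_recon():
    """A uptake -> A->B->C->D chain -> D export (7 reactions with boundary)."""
    recon = make_recon(
        make_reaction("R_AB", {"A_c": -1, "B_c": 1}, reversible=False),
        make_reaction("R_BC", {"B_c": -1, "C_c": 1}, reversible=False),
        make_reaction("R_CD", {"C_c": -1, "D_c": 1}, reversible=False),
    )
    from moltnet.reconstruct import add_transport_exchange
    add_transport_exchange(recon, ["A", "D"])
    return recon
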