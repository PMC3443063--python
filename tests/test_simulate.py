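"""Media application, knockout propagation, FBA, and growth binarization."""

import numpy as np
import pytest

from gemproject import gpr as G
from gemproject import model as M
from gemproject import simulate as S
from oracles import lp_max_by_vertex_enumeration


def chain_model() -> M.MetabolicModel:
    """uptake(<=10) -> A -> biomass, unit stoichiometry."""
    m = M.MetabolicModel(id="chain")
    m.compartments["c"] = M.Compartment("c")
    for mid in ("a_c", "bio_c"):
        m.metabolites[mid] = M.Metabolite(mid, "c")
    m.reactions["EX_a"] = M.Reaction("EX_a", {"a_c": -1.0}, lower_bound=-10, upper_bound=1000)
    m.reactions["GROW"] = M.Reaction(
        "GROW", {"a_c": -1.0, "bio_c": 1.0}, lower_bound=0, upper_bound=1000,
        gpr=G.parse_gpr("g1"),
    )
    m.reactions["EX_bio"] = M.Reaction("EX_bio", {"bio_c": -1.0}, lower_bound=0, upper_bound=1000)
    m.biomass_reaction = "GROW"
    m.validate()
    return m


# ---------------------------------------------------------------------------
# FBA

def test_fba_simple_chain_optimum():
    sol = S.fba(chain_model())
    assert sol.status == "optimal"
    assert sol.objective == pytest.approx(10.0, abs=1e-6)


def test_fba_objective_downstream_of_closed_reaction_is_zero():
    m = chain_model()
    m.reactions["EX_a"].lower_bound = 0.0
    sol = S.fba(m)
    assert sol.objective == pytest.approx(0.0, abs=1e-9)


def test_fba_mass_balance_and_bounds_on_solution(scaffold, media_cfg):
    con = S.apply_media(scaffold, media_cfg.get("MED0"), media_cfg.base_bounds)
    sol = S.fba(con)
    Smat, bounds, rxn_ids = S.build_lp(con)
    v = np.array([sol.fluxes[r] for r in rxn_ids])
    assert np.abs(Smat @ v).max() < 1e-6
    for x, (lb, ub) in zip(v, bounds):
        assert lb - 1e-6 <= x <= ub + 1e-6


def test_fba_invariant_under_reaction_insertion_order():
    m = chain_model()
    shuffled = M.MetabolicModel(id="shuffled", compartments=m.compartments,
                                metabolites=m.metabolites)
    for rid in reversed(list(m.reactions)):
        shuffled.reactions[rid] = m.reactions[rid]
    shuffled.biomass_reaction = m.biomass_reaction
    assert S.fba(shuffled).objective == pytest.approx(S.fba(m).objective, abs=1e-9)


@pytest.mark.parametrize("seed", range(6))
def test_fba_matches_vertex_enumeration_on_toy_networks(seed):
    """Random <=6-reaction networks: HiGHS optimum equals the enumeration
    oracle over basic feasible solutions."""
    rng = np.random.default_rng(seed)
    n_mets, n_rxns = 3, 6
    m = M.MetabolicModel(id=f"rand{seed}")
    m.compartments["c"] = M.Compartment("c")
    for i in range(n_mets):
        m.metabolites[f"x{i}_c"] = M.Metabolite(f"x{i}_c", "c")
    # one uptake, one sink, random internal topology
    m.reactions["IN"] = M.Reaction("IN", {"x0_c": 1.0}, lower_bound=0, upper_bound=10)
    m.reactions["OUT"] = M.Reaction(
        "OUT", {f"x{n_mets - 1}_c": -1.0}, lower_bound=0, upper_bound=1000
    )
    for j in range(n_rxns - 2):
        a, b = rng.choice(n_mets, size=2, replace=False)
        lb = 0.0 if rng.random() < 0.5 else -float(rng.integers(1, 20))
        m.reactions[f"R{j}"] = M.Reaction(
            f"R{j}",
            {f"x{a}_c": -1.0, f"x{b}_c": float(rng.integers(1, 3))},
            lower_bound=lb,
            upper_bound=float(rng.integers(1, 20)),
        )
    m.biomass_reaction = "OUT"
    m.validate()
    sol = S.fba(m)
    Smat, bounds, rxn_ids = S.build_lp(m)
    c = np.zeros(len(rxn_ids))
    c[rxn_ids.index("OUT")] = 1.0
    oracle = lp_max_by_vertex_enumeration(Smat.toarray(), bounds, c)
    assert sol.status == "optimal"
    assert sol.objective == pytest.approx(oracle, abs=1e-6)


# ---------------------------------------------------------------------------
# media

def test_apply_media_opens_only_named_carbon(scaffold, media_cfg):
    con = S.apply_media(scaffold, media_cfg.get("MED0"), media_cfg.base_bounds)
    assert con.reactions["EX_carb0"].lower_bound == -10.0
    for i in range(1, 6):
        assert con.reactions[f"EX_carb{i}"].lower_bound == 0.0
    assert con.reactions["EX_nh4"].lower_bound == -1000.0
    assert S.fba(con).objective > 0


def test_base_alone_gives_no_growth(scaffold, media_cfg):
    empty = S.MediaCondition("base-only", {})
    con = S.apply_media(scaffold, empty, media_cfg.base_bounds)
    assert S.fba(con).objective == pytest.approx(0.0, abs=1e-9)


def test_alternative_carbon_source_supports_growth(scaffold, media_cfg):
    con = S.apply_media(scaffold, media_cfg.get("MED3"), media_cfg.base_bounds)
    assert S.fba(con).objective > 0.1


def test_apply_media_unknown_exchange_errors(scaffold):
    with pytest.raises(KeyError, match="EX_nope"):
        S.apply_media(scaffold, S.MediaCondition("bad", {"EX_nope": (-10, 0)}))


def test_media_config_tsv_roundtrip(tmp_path, media_cfg):
    p = tmp_path / "media.tsv"
    with p.open("w") as fh:
        fh.write("medium\texchange\tlower\tupper\n")
        for ex, (lb, ub) in media_cfg.base_bounds.items():
            fh.write(f"base\t{ex}\t{lb}\t{ub}\n")
        for name, cond in media_cfg.presets.items():
            for ex, (lb, ub) in cond.exchange_bounds.items():
                fh.write(f"{name}\t{ex}\t{lb}\t{ub}\n")
    back = S.load_media_config(p)
    assert back.base_bounds == media_cfg.base_bounds
    assert {n: c.exchange_bounds for n, c in back.presets.items()} == {
        n: c.exchange_bounds for n, c in media_cfg.presets.items()
    }


# ---------------------------------------------------------------------------
# knockouts

def test_knockout_single_gene_closes_reaction():
    m = chain_model()
    ko = S.knockout(m, {"g1"})
    assert (ko.reactions["GROW"].lower_bound, ko.reactions["GROW"].upper_bound) == (0, 0)
    assert S.fba(ko).objective == pytest.approx(0.0, abs=1e-9)


def test_knockout_one_isozyme_keeps_reaction():
    m = chain_model()
    m.reactions["GROW"].gpr = G.parse_gpr("g1 or g2")
    ko = S.knockout(m, {"g1"})
    assert ko.reactions["GROW"].upper_bound == 1000


def test_knockout_empty_set_is_identity(scaffold):
    assert M.models_isomorphic(scaffold, S.knockout(scaffold, set()))


def test_knockout_disabled_set_matches_bruteforce_gpr_eval(scaffold):
    rng = np.random.default_rng(7)
    genes = sorted(scaffold.genes)
    for _ in range(20):
        deleted = set(rng.choice(genes, size=rng.integers(1, 8), replace=False))
        ko = S.knockout(scaffold, deleted)
        disabled = {
            rid
            for rid, rxn in ko.reactions.items()
            if (rxn.lower_bound, rxn.upper_bound) == (0, 0)
            and scaffold.reactions[rid].upper_bound != 0
        }
        # brute force: a reaction dies iff no minimal gene set survives
        expected = set()
        for rid, rxn in scaffold.reactions.items():
            if rxn.gpr is None:
                continue
            sets = G.minimal_gene_sets(rxn.gpr)
            if not any(s.isdisjoint(deleted) for s in sets):
                expected.add(rid)
        assert disabled == expected


def test_knockout_is_monotone(scaffold):
    small = S.knockout(scaffold, {"SC_G0001"})
    large = S.knockout(scaffold, {"SC_G0001", "SC_G0002", "SC_G0003"})
    for rid in scaffold.reactions:
        if (small.reactions[rid].lower_bound, small.reactions[rid].upper_bound) == (0, 0):
            assert (large.reactions[rid].lower_bound, large.reactions[rid].upper_bound) == (0, 0)


# ---------------------------------------------------------------------------
# binarization

@pytest.mark.parametrize(
    "rate,threshold,expected",
    [(0.0, 1e-6, False), (0.2, 1e-6, True), (1e-6, 1e-6, False)],  # strict at threshold
)
def test_binarize_growth_absolute(rate, threshold, expected):
    assert S.binarize_growth(rate, threshold) is expected


def test_binarize_growth_relative_to_wild_type():
    assert S.binarize_growth(0.06, threshold=0.1, reference_rate=0.5) is True
    assert S.binarize_growth(0.04, threshold=0.1, reference_rate=0.5) is False


def test_binarize_experiment_cohort_third_rule():
    cohort = [[0.9, 0.9], [0.9, 0.9], [0.06, 0.06]]
    # cohort mean 0.62 -> threshold ~0.207
    assert S.binarize_experiment(cohort[0], cohort) is True
    assert S.binarize_experiment(cohort[2], cohort) is False
    # all-equal curves are all called growing; flat zero in a growing cohort is not
    same = [[0.5, 0.5]] * 3
    assert S.binarize_experiment(same[0], same) is True
    assert S.binarize_experiment([0.0, 0.0], [[0.6, 0.6], [0.0, 0.0]]) is False
    with pytest.raises(ValueError):
        S.binarize_experiment([0.5], [])


def test_fba_objective_matches_cobrapy_on_fixture(tmp_path, scaffold, media_cfg):
    """Independent cross-check: cobrapy reads our SBML dialect and its FBA
    optimum matches ours under the same medium bounds."""
    cobra = pytest.importorskip("cobra")
    import warnings

    con = S.apply_media(scaffold, media_cfg.get("MED0"), media_cfg.base_bounds)
    path = tmp_path / "scaffold_med0.xml"
    M.write_sbml(con, path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cm = cobra.io.read_sbml_model(str(path))
    cm.objective = "BIOMASS"
    ours = S.fba(con).objective
    theirs = cm.slim_optimize()
    assert ours == pytest.approx(theirs, abs=1e-6)
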