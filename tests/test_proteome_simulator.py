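"""Codon-model simulation: rate matrix identities, parameter recovery,
indel parsimony against exhaustive enumeration, and process invariants."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest
from scipy import stats
from scipy.linalg import expm
from scipy.special import zeta

from evonet.data_io import CodonAlignment, Phylogeny
from evonet.proteome_simulator import (
    CODON_AA,
    GeneModel,
    IndelEvent,
    IndelModel,
    M0Params,
    SENSE_CODONS,
    build_m0_generator,
    count_indel_events,
    counting_dnds,
    encode_cds,
    fit_power_law,
    simulate_gene,
    simulate_replicates,
    translate,
)
from evonet.synthetic_data import back_translate

from conftest import SPECIES, random_protein


@pytest.fixture(scope="module")
def params():
    return M0Params(kappa=2.0, omega=0.2)


class TestM0Generator:
    def test_rows_sum_to_zero_and_rate_is_scaled(self, params):
        q = build_m0_generator(params)
        assert np.abs(q.sum(axis=1)).max() < 1e-12
        mean_rate = -(params.pi * np.diag(q)).sum()
        assert mean_rate == pytest.approx(1.0)

    def test_multi_position_changes_have_rate_zero(self, params):
        q = build_m0_generator(params)
        for u, cu in enumerate(SENSE_CODONS[:10]):
            for v, cv in enumerate(SENSE_CODONS):
                ndiff = sum(x != y for x, y in zip(cu, cv))
                if ndiff > 1:
                    assert q[u, v] == 0.0

    def test_omega_zero_kills_every_nonsynonymous_entry(self):
        q = build_m0_generator(M0Params(kappa=2.0, omega=0.0))
        for u, cu in enumerate(SENSE_CODONS):
            for v, cv in enumerate(SENSE_CODONS):
                if u != v and CODON_AA[u] != CODON_AA[v]:
                    assert q[u, v] == 0.0

    def test_detailed_balance(self, params):
        q = build_m0_generator(params)
        flux = params.pi[:, None] * q
        assert np.abs(flux - flux.T).max() < 1e-15

    def test_stationary_distribution_reached(self, params):
        q = build_m0_generator(params)
        p_inf = expm(q * 200.0)
        for row in p_inf[::13]:
            assert np.abs(row - params.pi).max() < 1e-6

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            M0Params(kappa=0.0, omega=0.2)
        with pytest.raises(ValueError):
            M0Params(kappa=2.0, omega=-0.1)
        with pytest.raises(ValueError):
            M0Params(kappa=2.0, omega=0.2, pi=np.full(61, 0.5))


class TestPowerLawFit:
    def draw(self, alpha, n, rng, xmax=400):
        k = np.arange(1, xmax + 1, dtype=float)
        pmf = k ** (-alpha)
        pmf /= pmf.sum()
        return rng.choice(np.arange(1, xmax + 1), size=n, p=pmf)

    def test_parameter_recovery(self, rng):
        draws = self.draw(2.5, 10_000, rng)
        assert fit_power_law(draws) == pytest.approx(2.5, abs=0.1)

    def test_equals_grid_search_oracle(self, rng):
        draws = self.draw(1.8, 2_000, rng)
        alpha_hat = fit_power_law(draws)
        grid = np.linspace(1.05, 5.0, 4000)
        loglik = [-len(draws) * math.log(zeta(a)) - a * np.log(draws).sum() for a in grid]
        assert alpha_hat == pytest.approx(grid[int(np.argmax(loglik))], abs=2e-3)

    @pytest.mark.parametrize("bad", [[], [1, 1, 1, 1], [7] * 20])
    def test_degenerate_input_rejected(self, bad):
        with pytest.raises(ValueError, match="degenerate"):
            fit_power_law(bad)

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError, match="at least 10"):
            fit_power_law([1, 2, 3])


def make_alignment(gaps: dict[str, list[tuple[int, int]]], n_codons=20) -> CodonAlignment:
    """Alignment of identical sequences with gap runs [start_col, end_col)."""
    base = "ATG" + "GCT" * (n_codons - 1)
    rows = {}
    for sp in SPECIES:
        row = list(base)
        for start, end in gaps.get(sp, []):
            row[start:end] = "-" * (end - start)
        rows[sp] = "".join(row)
    return CodonAlignment(gene_id="g", rows=rows)


class TestIndelParsimony:
    def test_gap_free_alignment_has_no_events(self, ladder_tree):
        assert count_indel_events(make_alignment({}), ladder_tree) == []

    def test_single_taxon_gap_is_one_pendant_deletion(self, ladder_tree):
        aln = make_alignment({"Spar": [(9, 18)]})  # 3 codons
        events = count_indel_events(aln, ladder_tree)
        assert len(events) == 1
        ev = events[0]
        assert (ev.branch, ev.kind, ev.length) == ("Spar", "deletion", 3)

    def test_sister_pair_gap_maps_to_ancestral_branch(self, ladder_tree):
        aln = make_alignment({"Spar": [(9, 18)], "Scer": [(9, 18)]})
        events = count_indel_events(aln, ladder_tree)
        assert len(events) == 1
        assert events[0].kind == "deletion"
        # the branch is the internal node ancestral to exactly {Spar, Scer}
        node = next(
            n for n in ladder_tree.postorder() if n.label == events[0].branch
        )
        clade = {leaf.label for leaf in ladder_tree.postorder() if leaf.is_leaf}

        def leaves_below(n):
            return {x.label for x in Phylogeny(n).leaves()} if not n.is_leaf else {n.label}

        assert leaves_below(node) == {"Spar", "Scer"}

    def test_event_count_matches_exhaustive_minimum_for_all_patterns(self, ladder_tree):
        internals = ladder_tree.internal_nodes()
        for pattern in itertools.product([0, 1], repeat=5):
            if not any(pattern):
                continue
            gaps = {
                sp: [(0, 3)] for sp, g in zip(sorted(SPECIES), pattern) if g
            }
            events = count_indel_events(make_alignment(gaps), ladder_tree)
            # oracle: exhaustive minimum over internal gap-state assignments
            leaf_state = dict(zip(sorted(SPECIES), pattern))
            best = 10**9
            for states in itertools.product([0, 1], repeat=len(internals)):
                assign = {n.label: s for n, s in zip(internals, states)}
                assign.update(leaf_state)
                changes = sum(
                    assign[n.label] != assign[n.parent.label]
                    for n in ladder_tree.postorder()
                    if n is not ladder_tree.root
                )
                best = min(best, changes)
            assert len(events) == best

    def test_partial_codon_runs_round_up(self, ladder_tree):
        # two Sbay runs of 2 and 4 columns (6 total keeps the row in frame)
        aln = make_alignment({"Sbay": [(9, 11), (20, 24)]})
        events = count_indel_events(aln, ladder_tree)
        assert sorted(e.length for e in events) == [1, 2]  # ceil(2/3), ceil(4/3)

    def test_leaf_mismatch_rejected(self, ladder_tree):
        aln = make_alignment({})
        aln.rows.pop("Sbay")
        with pytest.raises(ValueError, match="match"):
            count_indel_events(aln, ladder_tree)


class TestSimulateGene:
    def cds(self, rng, n=60):
        return back_translate(random_protein(rng, n), rng)

    def test_omega_zero_and_no_indels_preserve_every_protein(self, rng, sim_tree):
        cds = self.cds(rng)
        sim = simulate_gene(
            cds, sim_tree, M0Params(kappa=2.0, omega=0.0), IndelModel(rate=0.0),
            seed=5, root_label="Scer",
        )
        assert set(sim.proteins.values()) == {translate(cds)}

    def test_zero_branch_lengths_preserve_cds(self, rng, ladder_tree, params):
        cds = self.cds(rng)
        sim = simulate_gene(
            cds, ladder_tree, params, IndelModel(rate=0.1), seed=5, root_label="Scer"
        )
        assert set(sim.cds.values()) == {cds}

    def test_root_species_sequence_is_byte_identical(self, rng, sim_tree, params):
        cds = self.cds(rng)
        sim = simulate_gene(cds, sim_tree, params, IndelModel(rate=0.05), seed=9,
                            root_label="Scer")
        assert sim.cds["Scer"] == cds

    def test_deterministic_under_seed(self, rng, sim_tree, params):
        cds = self.cds(rng)
        runs = [
            simulate_gene(cds, sim_tree, params, IndelModel(rate=0.05), seed=7,
                          root_label="Scer")
            for _ in range(2)
        ]
        assert runs[0].cds == runs[1].cds
        assert runs[0].events == runs[1].events

    def test_outputs_translate_cleanly(self, rng, sim_tree, params):
        cds = self.cds(rng)
        sim = simulate_gene(cds, sim_tree, params, IndelModel(rate=0.05), seed=3,
                            root_label="Scer")
        for species, s in sim.cds.items():
            assert translate(s) == sim.proteins[species]

    def test_root_with_stop_rejected(self, sim_tree, params):
        with pytest.raises(ValueError, match="stop"):
            simulate_gene("ATGTAA", sim_tree, params, IndelModel(rate=0.0), seed=0,
                          root_label="Scer")

    def test_protected_codons_never_substituted(self, rng, sim_tree):
        cds = self.cds(rng, n=40)
        protected = np.zeros(40, dtype=bool)
        protected[10:30] = True
        hot = M0Params(kappa=2.0, omega=1.0)
        sim = simulate_gene(cds, sim_tree, hot, IndelModel(rate=0.0), seed=1,
                            root_label="Scer", protected_codons=protected)
        for s in sim.cds.values():
            assert s[30:90] == cds[30:90]


class TestSimulateReplicates:
    def models(self, rng, n_genes=6):
        genes = {}
        for g in range(n_genes):
            cds = back_translate(random_protein(rng, 40), rng)
            genes[f"g{g}"] = GeneModel(
                root_cds=cds,
                params=M0Params(kappa=2.0, omega=0.2),
                indels=IndelModel(rate=0.02),
            )
        return genes

    def test_replicates_are_deterministic_and_complete(self, rng, sim_tree):
        genes = self.models(rng)
        r1 = simulate_replicates(genes, sim_tree, 2, seed=5)
        r2 = simulate_replicates(genes, sim_tree, 2, seed=5)
        assert len(r1) == 2
        for a, b in zip(r1, r2):
            assert {s: p.sequences for s, p in a.proteomes.items()} == {
                s: p.sequences for s, p in b.proteomes.items()
            }
        for rep in r1:
            assert set(rep.proteomes) == set(SPECIES)
            assert all(len(p) == len(genes) for p in rep.proteomes.values())
            assert rep.proteomes["Scer"].sequences == {
                g: translate(m.root_cds) for g, m in genes.items()
            }

    def test_distinct_replicates_differ(self, rng, sim_tree):
        genes = self.models(rng, n_genes=10)
        reps = simulate_replicates(genes, sim_tree, 2, seed=5)
        seqs = [
            tuple(sorted(reps[i].proteomes["Sbay"].sequences.items())) for i in (0, 1)
        ]
        assert seqs[0] != seqs[1]

    def test_missing_params_rejected(self, rng, sim_tree):
        genes = self.models(rng, n_genes=1)
        genes["broken"] = GeneModel(root_cds="ATGGCT", params=None, indels=None)
        with pytest.raises(ValueError, match="broken"):
            simulate_replicates(genes, sim_tree, 1, seed=0)


class TestProcessInvariants:
    def test_substitution_locations_are_exchangeable(self, rng, sim_tree, params):
        """Counts in two disjoint equal codon intervals are exchangeable."""
        first = second = 0
        for g in range(200):
            cds = back_translate(random_protein(rng, 40), rng)
            sim = simulate_gene(cds, sim_tree, params, IndelModel(rate=0.0),
                                seed=10_000 + g, root_label="Scer")
            other = sim.cds["Sbay"]
            diffs = [
                i for i in range(40)
                if cds[3 * i : 3 * i + 3] != other[3 * i : 3 * i + 3]
            ]
            first += sum(1 for i in diffs if i < 20)
            second += sum(1 for i in diffs if i >= 20)
        total = first + second
        p = stats.binomtest(first, total, 0.5).pvalue
        assert p > 0.001

    def test_indel_event_count_is_poisson_with_the_nominal_mean(self, rng, sim_tree):
        model = IndelModel(rate=0.02)
        n_codons = 30
        counts = []
        cds = back_translate(random_protein(rng, n_codons), rng)
        for g in range(1000):
            sim = simulate_gene(cds, sim_tree, M0Params(kappa=2.0, omega=0.0),
                                model, seed=g, root_label="Scer")
            counts.append(len(sim.events))
        expected = model.rate * sim_tree.total_length() * n_codons
        mean = np.mean(counts)
        se = math.sqrt(expected / len(counts))
        assert abs(mean - expected) < 3 * se

    def test_indel_lengths_round_trip_through_parsimony_and_mle(self, rng, ladder_tree):
        """Planted power-law gap runs are recovered within 0.2 in alpha."""
        model = IndelModel(rate=0.02, alpha=2.0, max_length=30)
        pmf = model.length_pmf()
        taxa = sorted(SPECIES)
        internals = [n.label for n in ladder_tree.internal_nodes()
                     if n is not ladder_tree.root]
        branch_clades = {}
        for n in ladder_tree.postorder():
            if n is ladder_tree.root:
                continue
            clade = {x.label for x in Phylogeny(n).leaves()} if not n.is_leaf else {n.label}
            branch_clades[n.label] = clade
        branches = list(branch_clades)
        n_events = 400
        lengths = rng.choice(np.arange(1, model.max_length + 1), size=n_events, p=pmf)
        chosen = rng.choice(len(branches), size=n_events)
        rows = {sp: [] for sp in taxa}
        for length, b in zip(lengths, chosen):
            clade = branch_clades[branches[b]]
            for sp in taxa:
                block = "---" * length if sp in clade else "GCT" * length
                rows[sp].append(block + "ATG")  # spacer keeps runs separate
        aln = CodonAlignment(gene_id="g", rows={sp: "".join(v) for sp, v in rows.items()})
        events = count_indel_events(aln, ladder_tree)
        assert len(events) == n_events
        alpha_hat = fit_power_law([e.length for e in events])
        assert alpha_hat == pytest.approx(model.alpha, abs=0.2)


class TestCountingDnds:
    def test_identical_sequences_have_no_differences(self, rng):
        cds = back_translate(random_protein(rng, 50), rng)
        with pytest.raises(ValueError, match="dS is zero"):
            counting_dnds([(cds, cds)], kappa=2.0)

    def test_recovers_omega_on_simulated_genes(self, rng, sim_tree):
        params = M0Params(kappa=2.0, omega=0.2)
        pairs = []
        for g in range(300):
            cds = back_translate(random_protein(rng, 80), rng)
            sim = simulate_gene(cds, sim_tree, params, IndelModel(rate=0.0),
                                seed=g, root_label="Scer")
            pairs.append((cds, sim.cds["Sbay"]))
        _, _, omega = counting_dnds(pairs, kappa=2.0)
        assert omega == pytest.approx(0.2, abs=0.05)
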