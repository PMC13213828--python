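"""Symmetry-aware RMSD, capture curves, RMSF, confidence summaries."""

import itertools
import json

import numpy as np
import pytest
from hypothesis import given, strategies as hst

from pocketkit import BindingSite
from pocketkit import fixtures as fx
from pocketkit import site_metrics as sm
from pocketkit.structures import StructureModel


# --- independent brute-force oracle for the symmetry minimum ---------------

def brute_force_symmetry_rmsd(model, ref, site, include_prochiral=False):
    """Minimum side-chain RMSD over ALL explicit label-permutation combinations.

    Enumerates the global product of per-residue swap choices and computes
    each RMSD directly from coordinate arrays — independent of the
    per-residue decomposition used by the implementation.
    """
    table = dict(sm.SYMMETRY_GROUPS)
    if include_prochiral:
        for k, v in sm.PROCHIRAL_GROUPS.items():
            table.setdefault(k, []).extend(v)
    backbone = {"N", "CA", "C", "O", "OXT"}

    def sidechain(structure, key):
        a = structure.atoms
        mask = (a.chain_id == key[0]) & (a.res_id == key[1])
        return {
            str(a.atom_name[i]): np.asarray(a.coord[i], dtype=float)
            for i in np.nonzero(mask)[0]
            if str(a.atom_name[i]) not in backbone
            and str(a.element[i]).upper() not in {"H", "D"}
        }

    residues = site.sorted()
    m_atoms = {k: sidechain(model, k) for k in residues}
    r_atoms = {k: sidechain(ref, k) for k in residues}
    res_names = {}
    for k in residues:
        a = ref.atoms
        mask = (a.chain_id == k[0]) & (a.res_id == k[1])
        res_names[k] = str(a.res_name[mask][0])

    # per-residue swap options: list of mappings (identity or the group swaps)
    options = []
    for k in residues:
        names = set(m_atoms[k]) & set(r_atoms[k])
        groups = [
            g for g in table.get(res_names[k], [])
            if all(x in names and y in names for x, y in g)
        ]
        maps = [{}]
        for flags in itertools.product((False, True), repeat=len(groups)):
            if not any(flags):
                continue
            mp = {}
            for g, on in zip(groups, flags):
                if on:
                    for x, y in g:
                        mp[x], mp[y] = y, x
            maps.append(mp)
        options.append((k, sorted(names), maps))

    best = np.inf
    for combo in itertools.product(*(maps for _, _, maps in options)):
        total, n = 0.0, 0
        for (k, names, _), mp in zip(options, combo):
            for nm in names:
                d = m_atoms[k][nm] - r_atoms[k][mp.get(nm, nm)]
                total += float(d @ d)
                n += 1
        if n:
            best = min(best, np.sqrt(total / n))
    return best


def _perturbed(base, rng, scale=0.4):
    model = StructureModel(atoms=base.atoms.copy(), model_id="pert")
    model.atoms.coord = base.atoms.coord + rng.normal(
        0, scale, base.atoms.coord.shape)
    return model


class TestSymmetryRMSD:
    def test_identical_structures_give_zero(self, toy_protein, toy_site):
        r = sm.symmetry_rmsd(toy_protein, toy_protein, toy_site)
        assert r.value == 0.0
        assert r.swaps_applied == 0

    def test_label_swap_is_transparent(self, toy_protein, toy_site):
        # same geometry, ASP/GLU/ARG/PHE/TYR labels swapped: naive > 0, aware = 0
        swappable = {("A", 2), ("A", 3), ("A", 4), ("A", 5), ("A", 6)}
        swapped = fx.make_swap_fixture(toy_protein, swappable)
        r = sm.symmetry_rmsd(swapped, toy_protein, toy_site)
        assert r.naive_value > 0.1
        assert r.value < 1e-12
        assert r.swaps_applied == len(swappable)

    def test_never_exceeds_naive(self, toy_protein, toy_site, rng):
        for _ in range(10):
            model = _perturbed(toy_protein, rng)
            r = sm.symmetry_rmsd(model, toy_protein, toy_site)
            assert r.value <= r.naive_value + 1e-12

    def test_equals_brute_force_enumeration(self, toy_protein, rng):
        # k=5 swap-able residues -> 2^5 explicit permutations
        site = BindingSite(frozenset({("A", 2), ("A", 3), ("A", 4),
                                      ("A", 5), ("A", 6)}))
        for _ in range(8):
            model = _perturbed(toy_protein, rng)
            ours = sm.symmetry_rmsd(model, toy_protein, site).value
            oracle = brute_force_symmetry_rmsd(model, toy_protein, site)
            assert abs(ours - oracle) < 1e-9

    def test_backbone_class_has_no_symmetry(self, toy_protein, toy_site, rng):
        model = _perturbed(toy_protein, rng)
        r = sm.symmetry_rmsd(model, toy_protein, toy_site, atom_class="backbone")
        assert r.value == pytest.approx(r.naive_value)
        assert r.swaps_applied == 0
        assert r.n_atoms == 4 * len(toy_site)

    def test_prochiral_flag_enables_leu_val(self, toy_protein):
        site = BindingSite(frozenset({("A", 7), ("A", 8)}))  # LEU, VAL
        swapped = fx.make_swap_fixture(toy_protein, site.residues,
                                       include_prochiral=True)
        strict = sm.symmetry_rmsd(swapped, toy_protein, site)
        relaxed = sm.symmetry_rmsd(swapped, toy_protein, site,
                                   include_prochiral=True)
        assert strict.value > 0.1
        assert relaxed.value < 1e-12

    def test_residue_type_mismatch_skipped_with_warning(self, toy_protein):
        mutant = StructureModel(atoms=toy_protein.atoms.copy(), model_id="mut")
        mask = mutant.atoms.res_id == 2
        res_names = mutant.atoms.res_name.copy()
        res_names[mask] = "ALA"
        mutant.atoms.res_name = res_names
        site = BindingSite(frozenset({("A", 2), ("A", 5)}))
        with pytest.warns(UserWarning, match="mismatch"):
            r = sm.symmetry_rmsd(mutant, toy_protein, site)
        assert r.value == 0.0  # only residue 5 contributes, identical coords

    def test_empty_intersection_rejected(self, toy_protein):
        site = BindingSite(frozenset({("A", 10)}))  # GLY: no side chain
        with pytest.raises(ValueError, match="no shared"):
            sm.symmetry_rmsd(toy_protein, toy_protein, site)


class TestCaptureCurve:
    def test_all_captured_gives_unit_auc(self):
        curve = sm.capture_curve(np.full((3, 4), 0.5))
        assert np.all(curve.fractions == 1.0)
        assert curve.auc == pytest.approx(1.0)

    def test_none_captured_gives_zero_auc(self):
        curve = sm.capture_curve(np.full((3, 4), 3.0))
        assert np.all(curve.fractions == 0.0)
        assert curve.auc == 0.0

    def test_half_captured_flat_half_auc(self):
        curve = sm.capture_curve(np.array([[0.5], [9.9]]))
        assert np.all(curve.fractions == 0.5)
        assert curve.auc == pytest.approx(0.5)

    def test_min_over_models_semantics(self):
        # one good model rescues the structure at every threshold
        curve = sm.capture_curve(np.array([[4.0, 0.8, 6.0]]))
        assert np.all(curve.fractions == 1.0)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            sm.capture_curve(np.empty((0, 0)))

    @given(hst.integers(0, 2**31 - 1))
    def test_fractions_monotone_on_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        table = rng.uniform(0.2, 3.0, size=(rng.integers(1, 6),
                                            rng.integers(1, 6)))
        curve = sm.capture_curve(table)
        assert np.all(np.diff(curve.fractions) >= 0)
        assert 0.0 <= curve.auc <= 1.0

    def test_auc_stable_under_grid_refinement(self, rng):
        # halving the step changes the AUC by < 1e-3 on smooth tables
        table = rng.uniform(0.8, 2.2, size=(20000, 5))
        coarse = sm.capture_curve(table, sm.default_thresholds(step=0.05))
        fine = sm.capture_curve(table, sm.default_thresholds(step=0.025))
        assert abs(coarse.auc - fine.auc) < 1e-3


class TestEnsembleRMSF:
    def test_identical_models_have_zero_rmsf(self, toy_protein, toy_site):
        models = fx.make_toy_ensemble(toy_protein, {}, 3, seed=0)
        profile = sm.ensemble_rmsf(models, toy_site)
        assert all(v < 1e-6 for v in profile.per_residue.values())

    def test_two_models_single_displacement_gives_half_d(self, toy_protein):
        keys = toy_protein.residue_keys()
        site = BindingSite(frozenset(keys))
        a = StructureModel(atoms=toy_protein.atoms.copy(), model_id="a")
        b = StructureModel(atoms=toy_protein.atoms.copy(), model_id="b")
        # displace one side-chain atom by d; anchor elsewhere is untouched
        idx = int(np.nonzero((b.atoms.atom_name == "OD1")
                             & (b.atoms.res_id == 2))[0][0])
        d = 0.8
        coord = b.atoms.coord.copy()
        coord[idx] += [0.0, 0.0, d]
        b.atoms.coord = coord
        profile = sm.ensemble_rmsf([a, b], site, atom_class="sidechain")
        moved = profile.per_atom[("A", 2, "OD1")]
        assert moved == pytest.approx(d / 2, rel=0.02)

    def test_gaussian_noise_recovers_sigma_sqrt3(self, toy_protein):
        keys = toy_protein.residue_keys()
        sigma = 0.5
        profile_in = {("A", 5): sigma}
        models = fx.make_toy_ensemble(toy_protein, profile_in, 600, seed=9)
        site = BindingSite(frozenset(keys))
        out = sm.ensemble_rmsf(models, site, atom_class="sidechain")
        expected = sigma * np.sqrt(3)
        for name in ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"):
            got = out.per_atom[("A", 5, name)]
            assert abs(got - expected) / expected < 0.05

    def test_invariant_to_common_rigid_transform(self, toy_protein, toy_site):
        from scipy.spatial.transform import Rotation
        models = fx.make_toy_ensemble(toy_protein, {("A", 4): 0.3}, 20, seed=4)
        base = sm.ensemble_rmsf(models, toy_site)
        rot = Rotation.from_euler("xyz", [0.3, 0.6, -0.2]).as_matrix()
        moved = []
        for m in models:
            mm = StructureModel(atoms=m.atoms.copy(), model_id=m.model_id)
            mm.atoms.coord = m.atoms.coord @ rot.T + [5.0, -3.0, 2.0]
            moved.append(mm)
        shifted = sm.ensemble_rmsf(moved, toy_site)
        for key, val in base.per_residue.items():
            assert shifted.per_residue[key] == pytest.approx(val, abs=1e-4)

    def test_fewer_than_two_models_rejected(self, toy_protein, toy_site):
        with pytest.raises(ValueError, match="2 models"):
            sm.ensemble_rmsf([toy_protein], toy_site)

    def test_mean_aggregate_leq_rms(self, toy_protein, toy_site):
        models = fx.make_toy_ensemble(toy_protein, {("A", 5): 0.4}, 30, seed=2)
        rms = sm.ensemble_rmsf(models, toy_site, aggregate="rms")
        mean = sm.ensemble_rmsf(models, toy_site, aggregate="mean")
        for key in rms.per_residue:
            assert mean.per_residue[key] <= rms.per_residue[key] + 1e-12


class TestRMSFCorrelation:
    def _profile(self, values):
        return sm.RMSFProfile(
            per_residue={("A", i + 1): v for i, v in enumerate(values)},
            per_atom={}, atom_class="sidechain", n_models=2)

    def test_self_correlation_is_one(self):
        a = self._profile([0.1, 0.5, 0.9, 0.3])
        assert sm.rmsf_correlation(a, a) == pytest.approx(1.0)

    def test_anti_correlation_is_minus_one(self):
        a = self._profile([0.1, 0.5, 0.9, 0.3])
        b = self._profile([1.0 - v for v in [0.1, 0.5, 0.9, 0.3]])
        assert sm.rmsf_correlation(a, b) == pytest.approx(-1.0)

    def test_matches_covariance_formula(self, rng):
        xs, ys = rng.uniform(0, 1, 20), rng.uniform(0, 1, 20)
        a, b = self._profile(xs), self._profile(ys)
        cov = np.mean((xs - xs.mean()) * (ys - ys.mean()))
        expected = cov / (xs.std() * ys.std())
        assert sm.rmsf_correlation(a, b) == pytest.approx(expected, abs=1e-12)

    def test_too_few_shared_residues_rejected(self):
        a, b = self._profile([0.1, 0.2]), self._profile([0.3, 0.4])
        with pytest.raises(ValueError, match="3"):
            sm.rmsf_correlation(a, b)

    def test_zero_variance_rejected(self):
        a = self._profile([0.5, 0.5, 0.5])
        b = self._profile([0.1, 0.2, 0.3])
        with pytest.raises(ValueError, match="variance"):
            sm.rmsf_correlation(a, b)


class TestConfidenceSummary:
    def test_uniform_bfactor_gives_that_plddt(self, toy_protein):
        summary = sm.confidence_summary([toy_protein])
        assert summary.per_model_plddt[0] == pytest.approx(80.0)

    def test_constant_offdiagonal_pae(self, toy_protein):
        pae = np.full((10, 10), 5.0)
        np.fill_diagonal(pae, 0.0)
        summary = sm.confidence_summary([toy_protein], [pae])
        assert summary.per_model_pae[0] == pytest.approx(5.0)

    def test_median_over_three_models(self):
        models = [fx.make_toy_protein(bfactor=b, model_id=f"m{b}")
                  for b in (70.0, 80.0, 90.0)]
        summary = sm.confidence_summary(models)
        assert summary.median_plddt == pytest.approx(80.0)
        assert sorted(summary.per_model_plddt) == [70.0, 80.0, 90.0]

    def test_out_of_range_plddt_warns(self):
        model = fx.make_toy_protein(bfactor=120.0)
        with pytest.warns(UserWarning, match="pLDDT"):
            sm.confidence_summary([model])

    def test_non_square_pae_rejected(self, toy_protein):
        with pytest.raises(ValueError, match="square"):
            sm.confidence_summary([toy_protein], [np.zeros((3, 4))])

    def test_pae_json_dialect(self, tmp_path):
        mat = [[0.0, 4.0], [6.0, 0.0]]
        p = tmp_path / "pae.json"
        p.write_text(json.dumps([{"predicted_aligned_error": mat}]))
        np.testing.assert_allclose(sm.read_pae_json(p), mat)
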