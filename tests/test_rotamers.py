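"""Rotamer library analysis: superposition, Boltzmann reweighting, X1/X2
selection and pair distance distributions."""

import numpy as np
import pytest

from labelsim.energy import ForceFieldParams
from labelsim.rotamers import (
    RotamerLibrary,
    RotamerPlacement,
    UnlabelableSiteError,
    generate_library,
    pair_distance_distribution,
    rla_probabilities,
    superpose_rotamer,
    x1x2_select,
)
from labelsim.structure import LabelSite
from labelsim.templates import classify_x1x2


class TestSuperpose:
    def test_identity(self, rng):
        coords = rng.normal(size=(10, 3))
        anchor = coords[:3]
        placed, rmsd = superpose_rotamer(coords, anchor, anchor)
        assert np.allclose(placed, coords, atol=1e-10)
        assert rmsd == pytest.approx(0.0, abs=1e-10)

    def test_pure_translation_recovered(self, rng):
        coords = rng.normal(size=(8, 3))
        anchor = coords[:3]
        placed, rmsd = superpose_rotamer(coords, anchor, anchor + [5.0, 0.0, 0.0])
        assert np.allclose(placed, coords + [5.0, 0.0, 0.0], atol=1e-10)
        assert rmsd == pytest.approx(0.0, abs=1e-10)

    def test_random_rigid_transform_with_noise(self, rng):
        coords = rng.normal(size=(12, 3)) * 3.0
        anchor = coords[:4]
        theta = 0.9
        rot = np.array(
            [[np.cos(theta), 0, np.sin(theta)], [0, 1, 0], [-np.sin(theta), 0, np.cos(theta)]]
        )
        target_anchor = anchor @ rot.T + [1.0, 2.0, -3.0]
        target_anchor_noisy = target_anchor + rng.normal(scale=0.01, size=target_anchor.shape)
        placed, rmsd = superpose_rotamer(coords, anchor, target_anchor_noisy)
        expected = coords @ rot.T + [1.0, 2.0, -3.0]
        assert np.abs(placed - expected).max() < 0.1
        assert rmsd < 0.02

    def test_collinear_anchor_rejected(self):
        coords = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [0, 1, 0]])
        with pytest.raises(ValueError, match="collinear"):
            superpose_rotamer(coords, coords[:3], coords[:3])


def make_toy_library(r1_template, dihedrals, populations):
    from labelsim.templates import CANONICAL_ANCHOR

    dihedrals = np.asarray(dihedrals, float)
    anchor_block = np.array(
        [CANONICAL_ANCHOR["N"], CANONICAL_ANCHOR["CA"], CANONICAL_ANCHOR["C"],
         CANONICAL_ANCHOR["CB"]]
    )
    coords = np.empty((len(dihedrals), 4 + len(r1_template.atom_specs), 3))
    for i, d in enumerate(dihedrals):
        conf = r1_template.build_conformer(d, CANONICAL_ANCHOR)
        coords[i, :4] = anchor_block
        coords[i, 4:] = conf.coordinates
    return RotamerLibrary(
        template=r1_template,
        dihedrals=dihedrals,
        coords=coords,
        populations=np.asarray(populations, float),
        atom_names=["N", "CA", "C", "CB"] + r1_template.atom_names,
    )


class TestRlaProbabilities:
    def test_zero_interaction_returns_intrinsic(self, small_library, single_helix):
        """With all epsilon = 0 the Boltzmann reweighting is the identity
        on the intrinsic populations."""
        structure, site = single_helix
        params = ForceFieldParams()
        params.element_table = {
            el: (0.0, rh) for el, (_, rh) in params.element_table.items()
        }
        placement = rla_probabilities(small_library, site, structure, params)
        assert np.allclose(placement.probabilities, small_library.populations, atol=1e-12)

    def test_two_rotamer_analytic(self, r1_template, single_helix, monkeypatch):
        """p0 = (1/2, 1/2), E = (0, kT ln 2) -> p = (2/3, 1/3)."""
        structure, site = single_helix
        lib = make_toy_library(
            r1_template, [[-60.0, -60.0, 180.0, 90.0, 0.0], [180.0, 60.0, 180.0, 90.0, 0.0]],
            [0.5, 0.5],
        )
        energies = iter([0.0, np.log(2.0)])
        monkeypatch.setattr(
            "labelsim.rotamers.label_environment_energy",
            lambda *a, **k: next(energies),
        )
        placement = rla_probabilities(lib, site, structure, ForceFieldParams(), temperature=298.0)
        assert np.allclose(placement.probabilities, [2.0 / 3.0, 1.0 / 3.0], atol=1e-12)

    def test_matches_weighting_formula_oracle(self, r1_template, single_helix, rng, monkeypatch):
        """5-rotamer toy with random energies: must equal the direct
        evaluation p_i = p0_i exp(-E_i) / sum_j p0_j exp(-E_j)."""
        structure, site = single_helix
        p0 = rng.dirichlet(np.ones(5))
        dihedrals = rng.uniform(-180, 180, size=(5, 5))
        lib = make_toy_library(r1_template, dihedrals, p0)
        energies = rng.uniform(-2.0, 5.0, size=5)
        it = iter(energies)
        monkeypatch.setattr(
            "labelsim.rotamers.label_environment_energy", lambda *a, **k: next(it)
        )
        placement = rla_probabilities(lib, site, structure, ForceFieldParams())
        expected = p0 * np.exp(-energies)
        expected /= expected.sum()
        assert np.allclose(placement.probabilities, expected, atol=1e-12)

    def test_invariant_under_energy_shift(self, r1_template, single_helix, rng, monkeypatch):
        structure, site = single_helix
        p0 = rng.dirichlet(np.ones(4))
        lib = make_toy_library(r1_template, rng.uniform(-180, 180, size=(4, 5)), p0)
        energies = rng.uniform(0.0, 3.0, size=4)
        out = []
        for shift in (0.0, 123.0):
            it = iter(energies + shift)
            monkeypatch.setattr(
                "labelsim.rotamers.label_environment_energy", lambda *a, **k: next(it)
            )
            out.append(rla_probabilities(lib, site, structure, ForceFieldParams()).probabilities)
        assert np.allclose(out[0], out[1], atol=1e-12)

    def test_cooling_concentrates_probability(self, r1_template, single_helix, rng, monkeypatch):
        """Entropy of the placement is non-increasing as T decreases."""
        structure, site = single_helix
        p0 = rng.dirichlet(np.ones(6))
        lib = make_toy_library(r1_template, rng.uniform(-180, 180, size=(6, 5)), p0)
        energies = rng.uniform(0.0, 4.0, size=6)

        def entropy_at(t):
            it = iter(energies)
            monkeypatch.setattr(
                "labelsim.rotamers.label_environment_energy", lambda *a, **k: next(it)
            )
            p = rla_probabilities(lib, site, structure, ForceFieldParams(), temperature=t).probabilities
            p = p[p > 0]
            return -np.sum(p * np.log(p))

        ent = [entropy_at(t) for t in (400.0, 298.0, 150.0, 50.0)]
        assert all(a >= b - 1e-9 for a, b in zip(ent, ent[1:]))

    def test_all_clashing_site_unlabelable(self, r1_template, single_helix, monkeypatch):
        from labelsim.energy import CLASH_ENERGY

        structure, site = single_helix
        lib = make_toy_library(
            r1_template, [[0.0, 0.0, 0.0, 0.0, 0.0]], [1.0]
        )
        monkeypatch.setattr(
            "labelsim.rotamers.label_environment_energy",
            lambda *a, **k: CLASH_ENERGY,
        )
        with pytest.raises(UnlabelableSiteError):
            rla_probabilities(lib, site, structure, ForceFieldParams())


class TestX1X2Select:
    def _placement(self, lib, probs):
        return RotamerPlacement(
            site=LabelSite("A", 10),
            library=lib,
            energies=np.zeros(len(probs)),
            probabilities=np.asarray(probs, float),
            partition_function=1.0,
            reporter_positions=np.arange(3 * len(probs), dtype=float).reshape(-1, 3),
        )

    def test_single_survivor_takes_all(self, r1_template):
        lib = make_toy_library(
            r1_template,
            [[-60.0, -65.0, 0.0, 0.0, 0.0], [60.0, 170.0, 0.0, 0.0, 0.0]],  # {m,m}, {p,t}
            [0.5, 0.5],
        )
        out = x1x2_select(self._placement(lib, [0.5, 0.5]))
        assert np.allclose(out.probabilities, [1.0, 0.0])

    def test_all_classes_allowed_is_identity(self, r1_template, rng):
        dihedrals = rng.uniform(-180, 180, size=(6, 5))
        p = rng.dirichlet(np.ones(6))
        lib = make_toy_library(r1_template, dihedrals, np.full(6, 1 / 6))
        allowed = {(a, b) for a in "mpt" for b in "mpt"}
        out = x1x2_select(self._placement(lib, p), allowed=allowed)
        assert np.allclose(out.probabilities, p)

    def test_matches_filter_then_normalize_oracle(self, r1_template, rng):
        dihedrals = rng.uniform(-180, 180, size=(10, 5))
        p = rng.dirichlet(np.ones(10))
        lib = make_toy_library(r1_template, dihedrals, np.full(10, 0.1))
        out = x1x2_select(self._placement(lib, p))
        allowed = {("m", "m"), ("t", "p")}
        mask = np.array([classify_x1x2(d) in allowed for d in dihedrals])
        if mask.any():
            expected = np.where(mask, p, 0.0)
            expected /= expected.sum()
            assert np.allclose(out.probabilities, expected, atol=1e-12)

    def test_no_survivor_raises(self, r1_template):
        lib = make_toy_library(r1_template, [[60.0, 170.0, 0.0, 0.0, 0.0]], [1.0])
        with pytest.raises(UnlabelableSiteError):
            x1x2_select(self._placement(lib, [1.0]))


class TestPairDistanceDistribution:
    def _placement_at(self, lib, positions, probs):
        return RotamerPlacement(
            site=LabelSite("A", 1),
            library=lib,
            energies=np.zeros(len(probs)),
            probabilities=np.asarray(probs, float),
            partition_function=1.0,
            reporter_positions=np.asarray(positions, float),
        )

    def test_single_rotamers_give_delta(self, small_library):
        a = self._placement_at(small_library, [[0.0, 0.0, 0.0]], [1.0])
        b = self._placement_at(small_library, [[30.0, 0.0, 0.0]], [1.0])
        d = pair_distance_distribution(a, b)
        assert d.probabilities.sum() == pytest.approx(1.0)
        peak = d.bin_centers[np.argmax(d.probabilities)]
        assert peak == pytest.approx(30.0, abs=d.bin_width)

    def test_two_by_two_enumeration_oracle(self, small_library):
        """Hand-set positions/probabilities: the histogram must equal the
        4-term weighted enumeration."""
        pa = [0.6, 0.4]
        pb = [0.7, 0.3]
        pos_a = [[0.0, 0.0, 0.0], [2.1, 0.0, 0.0]]
        pos_b = [[30.2, 0.0, 0.0], [40.4, 0.0, 0.0]]
        a = self._placement_at(small_library, pos_a, pa)
        b = self._placement_at(small_library, pos_b, pb)
        d = pair_distance_distribution(a, b)
        # enumeration oracle: 4 weighted distances binned by hand
        pairs = {30.2: 0.42, 28.1: 0.28, 40.4: 0.18, 38.3: 0.12}
        expected = np.zeros_like(d.probabilities)
        for r, w in pairs.items():
            expected[int((r - 10.0) // 0.5)] += w
        assert np.allclose(d.probabilities, expected, atol=1e-12)

    def test_symmetric_in_arguments(self, small_library, rng):
        pa = rng.dirichlet(np.ones(3))
        pb = rng.dirichlet(np.ones(4))
        a = self._placement_at(small_library, rng.normal(size=(3, 3)) * 5, pa)
        b = self._placement_at(small_library, rng.normal(size=(4, 3)) * 5 + 30, pb)
        d1 = pair_distance_distribution(a, b)
        d2 = pair_distance_distribution(b, a)
        assert np.allclose(d1.probabilities, d2.probabilities)


class TestGenerateLibrary:
    def test_populations_normalized_and_deterministic(self, small_library, r1_template):
        assert small_library.populations.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(small_library.populations >= 0)
        assert len(small_library) == 40
        again = generate_library(r1_template, n_rotamers=40, n_samples=4000, seed=7)
        assert np.array_equal(again.dihedrals, small_library.dihedrals)
        assert np.array_equal(again.populations, small_library.populations)

    def test_covers_x1x2_classes(self, small_library):
        classes = {classify_x1x2(d) for d in small_library.dihedrals}
        assert {("m", "m"), ("t", "p")} <= classes

    def test_end_to_end_site_distribution(self, small_library, helix_pair):
        """Full RLA on the two-helix scaffold: normalized distribution with
        support near the inter-helix separation."""
        structure, sites = helix_pair
        pa = rla_probabilities(small_library, sites[0], structure)
        pb = rla_probabilities(small_library, sites[1], structure)
        assert pa.probabilities.sum() == pytest.approx(1.0, abs=1e-9)
        d = pair_distance_distribution(pa, pb)
        assert d.probabilities.sum() == pytest.approx(1.0, abs=1e-9)
        from labelsim.diststats import summarize

        s = summarize(d)
        assert 15.0 < s.mean_cog < 45.0  # 30 A backbone separation +- label reach
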