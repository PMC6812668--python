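"""Templates, rigid torsion rotation, clash detection, entropy selection."""

import math

import numpy as np
import pytest

from rotasuite.catalog import TORSION_NAMES
from rotasuite.geometry import assign_rotamer, dihedral
from rotasuite.sampler import (
    ConformerSet,
    detect_clash,
    entropy_curve,
    sample_rotamer,
    select_sample_size,
    set_suite_torsions,
    set_torsion,
    shannon_entropy,
)
from rotasuite.templates import BASES, TemplateDefinitionError, build_template, enumerate_templates


def _bond_lengths(template, coords):
    return sorted(
        float(np.linalg.norm(coords[i] - coords[j])) for i, j in template.rigid_bonds
    )


def _bond_angles(template, coords):
    # angles at every atom between each pair of rigid-bond neighbours
    neigh = {}
    for i, j in template.rigid_bonds:
        neigh.setdefault(i, []).append(j)
        neigh.setdefault(j, []).append(i)
    out = []
    for centre, nbrs in neigh.items():
        for a in range(len(nbrs)):
            for b in range(a + 1, len(nbrs)):
                v1 = coords[nbrs[a]] - coords[centre]
                v2 = coords[nbrs[b]] - coords[centre]
                cosang = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
                out.append(math.degrees(math.acos(np.clip(cosang, -1, 1))))
    return sorted(out)


class TestTemplates:
    def test_sixteen_templates_enumerated(self):
        templates = enumerate_templates()
        assert len(templates) == 16
        assert set(templates) == {a + b for a in BASES for b in BASES}

    def test_all_suite_torsions_resolvable(self, template_aa):
        for name in TORSION_NAMES:
            idx = template_aa.torsion_atoms[name]
            assert len(idx) == 4
            assert len(template_aa.downstream_of(name)) > 0

    def test_undefined_torsion_raises(self, template_aa):
        with pytest.raises(TemplateDefinitionError):
            template_aa.downstream_of("chi")

    def test_ring_closure_is_chemically_sane(self, template_aa):
        for slot in (0, 1):
            o4 = template_aa.coords[template_aa.index_of(slot, "O4'")]
            c1 = template_aa.coords[template_aa.index_of(slot, "C1'")]
            assert 1.3 < np.linalg.norm(o4 - c1) < 1.6


class TestSetTorsion:
    def test_identity_rotation_leaves_coordinates(self, template_aa):
        name = "ga"
        i, j, k, l = template_aa.torsion_atoms[name]
        current = dihedral(*(template_aa.coords[x] for x in (i, j, k, l)))
        out = set_torsion(template_aa, template_aa.coords, name, current)
        assert np.allclose(out, template_aa.coords, atol=1e-9)

    @pytest.mark.parametrize("name", TORSION_NAMES)
    @pytest.mark.parametrize("target", [10.0, 123.4, 359.0])
    def test_round_trip(self, template_aa, name, target):
        out = set_torsion(template_aa, template_aa.coords, name, target)
        i, j, k, l = template_aa.torsion_atoms[name]
        got = dihedral(out[i], out[j], out[k], out[l])
        assert abs(((got - target + 180) % 360) - 180) < 1e-6

    def test_successive_rotations_commute_in_measured_torsions(self, template_aa):
        c1 = set_torsion(template_aa, template_aa.coords, "al", 70.0)
        c1 = set_torsion(template_aa, c1, "ga", 170.0)
        c2 = set_torsion(template_aa, template_aa.coords, "ga", 170.0)
        c2 = set_torsion(template_aa, c2, "al", 70.0)
        for coords in (c1, c2):
            for name, want in (("al", 70.0), ("ga", 170.0)):
                i, j, k, l = template_aa.torsion_atoms[name]
                got = dihedral(coords[i], coords[j], coords[k], coords[l])
                assert abs(((got - want + 180) % 360) - 180) < 1e-6

    def test_rigid_geometry_conservation(self, template_aa, catalog):
        ref_lengths = _bond_lengths(template_aa, template_aa.coords)
        ref_angles = _bond_angles(template_aa, template_aa.coords)
        for rid in ("1a", "2[", "5d", "1o"):
            coords = set_suite_torsions(
                template_aa, catalog.lookup(rid).mean_torsions
            )
            assert np.allclose(_bond_lengths(template_aa, coords), ref_lengths, atol=1e-6)
            assert np.allclose(_bond_angles(template_aa, coords), ref_angles, atol=1e-6)


class TestDetectClash:
    def _toy(self):
        # 6 atoms in a chain: graph distances 1..5 between ends
        coords = np.array([[float(i), 0, 0] for i in range(6)])
        gdist = np.abs(np.arange(6)[:, None] - np.arange(6)[None, :]).astype(float)
        radii = np.full(6, 1.7)
        return coords, gdist, radii

    def test_deep_overlap_beyond_three_bonds(self):
        coords, gdist, radii = self._toy()
        coords[5] = coords[0] + [0.5, 0, 0]  # 5 bonds apart, 0.5 A
        assert detect_clash(coords, gdist, radii) is True

    def test_pairs_within_three_bonds_never_counted(self):
        coords, gdist, radii = self._toy()
        coords[3] = coords[0] + [0.1, 0, 0]  # 3 bonds apart: excluded
        coords[2] = coords[0] + [0.05, 0.05, 0]
        assert detect_clash(coords, gdist, radii) is False

    def test_template_at_a_form_mean_is_clash_free(self, template_aa, catalog):
        coords = set_suite_torsions(template_aa, catalog.lookup("1a").mean_torsions)
        assert not detect_clash(
            coords,
            template_aa.graph_distances(),
            template_aa.vdw_radii(),
            countable=template_aa.countable_pairs(),
        )

    def test_unknown_element_raises(self, template_aa):
        with pytest.raises(KeyError):
            template_aa.vdw_radii({"C": 1.7})  # no O/N/P radii


class TestSampleRotamer:
    def test_zero_spread_returns_means(self, template_aa, catalog):
        rot = catalog.lookup("1a")
        from rotasuite.catalog import RotamerDef

        degenerate = RotamerDef(
            rot.rotamer_id, rot.mean_torsions, (1e-9,) * 7, rot.frequency
        )
        cs = sample_rotamer(template_aa, degenerate, 5, seed=0)
        assert cs.n_retained == 5
        assert np.allclose(cs.torsion_vectors, rot.mean_torsions, atol=1e-6)

    def test_fixed_seed_reproducible(self, template_aa, catalog):
        a = sample_rotamer(template_aa, catalog.lookup("1b"), 10, seed=42)
        b = sample_rotamer(template_aa, catalog.lookup("1b"), 10, seed=42)
        assert np.array_equal(a.torsion_vectors, b.torsion_vectors)
        assert a.n_generated == b.n_generated

    def test_counts_consistent(self, template_aa, catalog):
        cs = sample_rotamer(template_aa, catalog.lookup("2["), 15, seed=3)
        assert cs.n_retained == cs.n_generated - cs.n_clash_rejected

    def test_circular_means_near_catalog_means(self, template_aa, catalog):
        rot = catalog.lookup("1a")
        cs = sample_rotamer(template_aa, rot, 200, seed=7)
        ang = np.radians(cs.torsion_vectors)
        circ_mean = np.degrees(
            np.arctan2(np.sin(ang).mean(0), np.cos(ang).mean(0))
        ) % 360.0
        for got, mu, sd in zip(circ_mean, rot.mean_torsions, rot.spread_torsions):
            tol = 3.0 * sd / math.sqrt(cs.n_retained)
            assert abs(((got - mu + 180) % 360) - 180) < tol

    def test_retained_conformers_reassign_to_generator(self, template_aa, catalog):
        """>= 95% of sampled conformers assign back to the generating
        rotamer at catalog spreads (tail overlap causes the rest)."""
        total = miss = 0
        for rid in catalog.rotamer_ids:
            cs = sample_rotamer(template_aa, catalog.lookup(rid), 10, seed=11)
            for tv in cs.torsion_vectors:
                total += 1
                miss += assign_rotamer(tv, catalog)[0] != rid
        assert total > 400
        assert miss / total < 0.05

    def test_attempt_cap_returns_partial(self, template_aa, catalog):
        rot = catalog.lookup("1a")
        # an absurd overlap factor rejects everything
        cs = sample_rotamer(
            template_aa, rot, 5, seed=0, overlap_factor=10.0, attempt_factor=3
        )
        assert cs.partial and cs.n_retained < 5


class TestEntropy:
    def test_single_bin_is_zero(self):
        assert shannon_entropy([2.0, 3.0, 4.9]) == 0.0

    def test_uniform_k_bins_is_ln_k(self):
        values = [2.5 + 5.0 * k for k in range(12)]
        assert shannon_entropy(values) == pytest.approx(math.log(12))

    def test_two_bin_split(self):
        values = [1.0] * 75 + [7.0] * 25
        expected = -(0.75 * math.log(0.75) + 0.25 * math.log(0.25))
        assert shannon_entropy(values) == pytest.approx(expected)

    def test_support_bound(self):
        rng = np.random.default_rng(0)
        assert shannon_entropy(rng.uniform(0, 360, 100000)) <= math.log(72)

    def _pool(self, catalog, n=150):
        rot = catalog.lookup("1a")
        rng = np.random.default_rng(5)
        vectors = rng.normal(rot.mean_torsions, rot.spread_torsions, (n, 7)) % 360
        return ConformerSet("1a", "UU", vectors, n_generated=n, n_clash_rejected=0)

    def test_full_sample_is_100_percent(self, catalog):
        pool = self._pool(catalog)
        curve = entropy_curve(pool, [10, 150], replicates=5, seed=0)
        assert curve[-1][1] == pytest.approx(100.0)

    def test_single_conformer_is_zero_percent(self, catalog):
        pool = self._pool(catalog)
        (n, mean, lo, hi), = entropy_curve(pool, [1], replicates=3, seed=0)
        assert mean == 0.0

    def test_mean_percentage_nondecreasing(self, catalog):
        pool = self._pool(catalog)
        curve = entropy_curve(pool, range(5, 101, 5), replicates=50, seed=1)
        means = [m for _, m, _, _ in curve]
        # monotone up to replicate noise: allow tiny inversions only
        assert all(b >= a - 1.0 for a, b in zip(means, means[1:]))

    def test_oversized_sample_raises(self, catalog):
        pool = self._pool(catalog, n=20)
        with pytest.raises(ValueError):
            entropy_curve(pool, [21], replicates=2, seed=0)


class TestSelectSampleSize:
    def test_threshold_scan(self):
        assert select_sample_size([(5, 50.0), (40, 81.0), (100, 95.0)]) == 40

    def test_zero_cutoff_returns_smallest(self):
        assert select_sample_size([(5, 50.0), (40, 81.0)], cutoff_percent=0) == 5

    def test_unreachable_cutoff_falls_back_to_largest(self):
        assert select_sample_size([(5, 50.0), (40, 70.0)], cutoff_percent=99) == 40

    def test_selected_size_on_wrapped_normal_pool(self, catalog):
        """On a 1a-like pool with catalog spreads the 80% cutoff lands at a
        few tens of conformers (soft check; depends on spreads)."""
        rot = catalog.lookup("1a")
        rng = np.random.default_rng(9)
        vectors = rng.normal(rot.mean_torsions, rot.spread_torsions, (150, 7)) % 360
        pool = ConformerSet("1a", "UU", vectors, 150, 0)
        curve = entropy_curve(pool, range(5, 101, 5), replicates=30, seed=2)
        n = select_sample_size(curve, 80.0)
        assert 10 <= n <= 100
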