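"""Feature typing and model matching."""

import numpy as np
import pytest

from opsinscreen.geometry import apply_rigid, random_rigid
from opsinscreen.pharmacophore import (ExcludedVolume, FeatureKind,
                                       FeaturePoint, LigandConformer,
                                       PharmacophoreFeature,
                                       PharmacophoreModel, detect_features,
                                       match)

from _oracles import brute_force_match


def _formaldehyde():
    coords = np.array([[0.0, 0.0, 0.0], [1.22, 0.0, 0.0]])
    return LigandConformer("hcho", ["O", "C"], coords, [(0, 1, 2.0)])


def _propane():
    coords = np.array([[0.0, 0.0, 0.0], [1.5, 0.4, 0.0], [3.0, 0.0, 0.0]])
    return LigandConformer("propane", ["C"] * 3, coords,
                           [(0, 1, 1.0), (1, 2, 1.0)])


class TestDetectFeatures:
    def test_benzene_gives_one_hydrophobic_at_ring_centroid(self, benzene_conformer):
        pts = detect_features(benzene_conformer)
        hydro = [p for p in pts if p.kind == FeatureKind.HYDROPHOBIC]
        assert len(hydro) == 1
        assert np.allclose(hydro[0].position,
                           benzene_conformer.coords.mean(axis=0), atol=1e-9)
        assert not [p for p in pts if p.kind == FeatureKind.HBOND_ACCEPTOR]

    def test_carbonyl_oxygen_is_an_acceptor_at_its_position(self):
        pts = detect_features(_formaldehyde())
        acc = [p for p in pts if p.kind == FeatureKind.HBOND_ACCEPTOR]
        assert len(acc) == 1
        assert np.allclose(acc[0].position, (0.0, 0.0, 0.0))

    def test_propane_chain_gives_one_hydrophobic_at_chain_centroid(self):
        pts = detect_features(_propane())
        hydro = [p for p in pts if p.kind == FeatureKind.HYDROPHOBIC]
        assert len(hydro) == 1
        assert np.allclose(hydro[0].position,
                           _propane().coords.mean(axis=0), atol=1e-9)

    def test_amide_nitrogen_is_not_an_acceptor(self):
        # N-methylacetamide heavy atoms: the amide N must be excluded,
        # the carbonyl O kept
        coords = np.array([[0.0, 0.0, 0.0],   # C (methyl)
                           [1.5, 0.0, 0.0],   # C (carbonyl)
                           [2.1, 1.1, 0.0],   # O
                           [2.2, -1.2, 0.0],  # N
                           [3.6, -1.3, 0.0]])  # C (N-methyl)
        conf = LigandConformer("nma", ["C", "C", "O", "N", "C"], coords,
                               [(0, 1, 1.0), (1, 2, 2.0), (1, 3, 1.0),
                                (3, 4, 1.0)])
        acc = [p for p in detect_features(conf)
               if p.kind == FeatureKind.HBOND_ACCEPTOR]
        assert len(acc) == 1
        assert np.allclose(acc[0].position, coords[2])

    def test_empty_molecule_is_rejected(self):
        with pytest.raises(ValueError, match="no atoms"):
            LigandConformer("empty", [], np.zeros((0, 3)), [])


def _conformer_at_model_points(model, acceptor_shift=None):
    """Atoms placed exactly at the model feature centers: three benzene
    rings at the hydrophobic centers and a carbonyl at the acceptor."""
    symbols, coords, bonds = [], [], []
    for f in model.features:
        c = np.asarray(f.center, dtype=float)
        if f.kind == FeatureKind.HYDROPHOBIC:
            base = len(symbols)
            ang = np.arange(6) * np.pi / 3
            ring = np.stack([1.396 * np.cos(ang), 1.396 * np.sin(ang),
                             np.zeros(6)], axis=1) + c
            symbols += ["C"] * 6
            coords.append(ring)
            bonds += [(base + i, base + (i + 1) % 6, 1.5) for i in range(6)]
        else:
            if acceptor_shift is not None:
                c = c + np.asarray(acceptor_shift)
            base = len(symbols)
            symbols += ["O", "C"]
            coords.append(np.stack([c, c + np.array([0.0, 0.0, 1.22])]))
            bonds.append((base, base + 1, 2.0))
    return LigandConformer("probe", symbols, np.vstack(coords), bonds)


class TestMatch:
    def test_exact_placement_matches_with_zero_residual(self, model):
        res = match(model, _conformer_at_model_points(model))
        assert res.matched
        assert res.residual < 1e-6

    def test_acceptor_displaced_twice_tolerance_fails(self, model):
        tol = next(f.tolerance for f in model.features
                   if f.kind == FeatureKind.HBOND_ACCEPTOR)
        # displace radially away from the pocket centroid so no rigid
        # refit can absorb it
        acc = np.array(next(f.center for f in model.features
                            if f.kind == FeatureKind.HBOND_ACCEPTOR))
        centroid = np.mean([f.center for f in model.features], axis=0)
        d = (acc - centroid) / np.linalg.norm(acc - centroid)
        conf = _conformer_at_model_points(model, acceptor_shift=2 * tol * d)
        res = match(model, conf)
        assert not res.matched
        # the independent oracle agrees on this instance
        assert not brute_force_match(model, detect_features_list(conf),
                                     conf.heavy_coords)

    def test_heavy_atom_in_excluded_volume_fails(self, model):
        conf = _conformer_at_model_points(model)
        vol = model.volumes[0]
        symbols = list(conf.symbols) + ["C"]
        coords = np.vstack([conf.coords, np.asarray(vol.center)])
        clashing = LigandConformer("clash", symbols, coords, list(conf.bonds))
        assert match(model, clashing).matched is False
        assert match(model, conf).matched is True

    def test_no_candidate_feature_points_is_a_clean_non_match(self, model):
        # methane-like single carbon: no features at all
        conf = LigandConformer("c1", ["C"], np.zeros((1, 3)), [])
        res = match(model, conf)
        assert res.matched is False

    def test_rigid_invariance_of_the_match_flag(self, model):
        rng = np.random.default_rng(11)
        matched_conf = _conformer_at_model_points(model)
        tol = 1.5
        acc = np.array(next(f.center for f in model.features
                            if f.kind == FeatureKind.HBOND_ACCEPTOR))
        centroid = np.mean([f.center for f in model.features], axis=0)
        d = (acc - centroid) / np.linalg.norm(acc - centroid)
        unmatched_conf = _conformer_at_model_points(
            model, acceptor_shift=2 * tol * d)
        for conf, expected in ((matched_conf, True), (unmatched_conf, False)):
            for _ in range(25):
                R, t = random_rigid(rng)
                assert match(model, conf.transformed(R, t)).matched is expected

    def test_adding_excluded_volumes_never_creates_a_match(self, model):
        rng = np.random.default_rng(3)
        conf = _conformer_at_model_points(model)
        base = PharmacophoreModel(list(model.features), [])
        previous = match(base, conf).matched
        vols = []
        for _ in range(10):
            vols.append(ExcludedVolume(tuple(rng.uniform(-8, 8, 3)),
                                       float(rng.uniform(0.5, 2.0))))
            now = match(PharmacophoreModel(list(model.features), list(vols)),
                        conf).matched
            assert not (now and not previous)  # false -> true is impossible
            previous = now

    def test_agreement_with_brute_force_oracle_on_random_instances(self, model):
        rng = np.random.default_rng(29)
        for trial in range(150):
            n_pts = int(rng.integers(2, 7))
            pts = []
            for i in range(n_pts):
                kind = (FeatureKind.HYDROPHOBIC if rng.random() < 0.7
                        else FeatureKind.HBOND_ACCEPTOR)
                if rng.random() < 0.6:
                    # near a model feature: matches and near-misses occur
                    f = model.features[int(rng.integers(4))]
                    pos = tuple(np.asarray(f.center) + rng.normal(0, 1.2, 3))
                else:
                    pos = tuple(rng.uniform(-6, 7, 3))
                pts.append(FeaturePoint(kind, pos, (i,)))
            heavy = np.array([p.position for p in pts])
            conf = LigandConformer(
                f"t{trial}", ["C"] * n_pts, heavy, [])
            got = match(model, conf, feature_points=pts).matched
            want = brute_force_match(model, pts, heavy)
            assert got == want


def detect_features_list(conf):
    from opsinscreen.pharmacophore import detect_features
    return detect_features(conf)


class TestModelValidation:
    def test_model_requires_three_hydrophobic_and_one_acceptor(self):
        f = PharmacophoreFeature(FeatureKind.HYDROPHOBIC, (0, 0, 0), 1.5)
        with pytest.raises(ValueError):
            PharmacophoreModel([f, f, f, f])

    def test_tolerance_and_radius_must_be_positive(self):
        with pytest.raises(ValueError):
            PharmacophoreFeature(FeatureKind.HYDROPHOBIC, (0, 0, 0), 0.0)
        with pytest.raises(ValueError):
            ExcludedVolume((0, 0, 0), -1.0)

    def test_model_json_round_trip(self, model, tmp_path):
        path = tmp_path / "model.json"
        model.save(path)
        loaded = PharmacophoreModel.load(path)
        assert np.allclose(loaded.centers, model.centers)
        assert len(loaded.volumes) == len(model.volumes)
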