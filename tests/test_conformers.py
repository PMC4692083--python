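"""Dihedral Monte-Carlo sampling, conformer attachment, clash checks."""

import numpy as np
import pytest

import flexsas as fx
from flexsas.conformers import (
    ConformerLibraryEntry,
    EnsembleRecord,
    FlexibleSegmentSpec,
    add_o_glycans,
    attach_conformers,
    sample_hinge,
)
from flexsas.models import AtomisticModel, clash_check
from flexsas.peptide import build_backbone


def backbone(seq="A" * 12, **kw):
    return build_backbone(seq, segment="hinge", **kw)


class TestSampleHinge:
    def test_zero_step_limits_reproduce_input(self):
        m = backbone()
        spec = [FlexibleSegmentSpec("A", 2, 11, 0.0, 0.0)]
        ens, recs = sample_hinge(m, spec, 3, seed=1)
        for e in ens:
            assert np.allclose(e.coords, m.coords, atol=1e-12)

    def test_same_seed_is_bit_reproducible(self):
        m = backbone()
        spec = [FlexibleSegmentSpec("A", 2, 11, 10.0, 30.0)]
        e1, r1 = sample_hinge(m, spec, 5, seed=42)
        e2, r2 = sample_hinge(m, spec, 5, seed=42)
        for a, b in zip(e1, e2):
            assert np.array_equal(a.coords, b.coords)
        assert [r.moves for r in r1] == [r.moves for r in r2]
        e3, _ = sample_hinge(m, spec, 5, seed=43)
        assert not np.array_equal(e1[0].coords, e3[0].coords)

    def test_upstream_atoms_do_not_move(self):
        m = backbone("A" * 20)
        spec = [FlexibleSegmentSpec("A", 10, 15, 10.0, 30.0)]
        ens, _ = sample_hinge(m, spec, 3, seed=0)
        fixed = m.resid < 10
        for e in ens:
            assert np.allclose(e.coords[fixed], m.coords[fixed], atol=1e-12)

    def test_downstream_rigid_body_is_rigid(self):
        """Atoms past the segment move only by a rigid transformation."""
        from flexsas.models import kabsch

        m = backbone("A" * 24)
        spec = [FlexibleSegmentSpec("A", 5, 8, 10.0, 30.0)]
        ens, _ = sample_hinge(m, spec, 2, seed=3)
        tail = m.resid > 9
        for e in ens:
            _, _, rmsd = kabsch(e.coords[tail], m.coords[tail])
            assert rmsd < 1e-10

    def test_bond_geometry_preserved(self):
        m = backbone()
        spec = [FlexibleSegmentSpec("A", 2, 11, 10.0, 30.0)]
        ens, _ = sample_hinge(m, spec, 2, seed=5)
        for e in ens:
            d0 = np.linalg.norm(np.diff(m.coords, axis=0), axis=1)
            d1 = np.linalg.norm(np.diff(e.coords, axis=0), axis=1)
            assert np.allclose(d0, d1, atol=1e-9)

    def test_free_segment_distance_distribution_matches_direct_oracle(self):
        """Uniform +/-180 deg MC equals direct uniform dihedral builds."""
        from scipy.stats import ks_2samp

        n = 3000
        m = backbone("A" * 10, with_cb=False)
        spec = [FlexibleSegmentSpec("A", 1, 10, 180.0, 180.0)]
        ens, _ = sample_hinge(m, spec, n, seed=11, clash_cutoff=0.0)
        ca = [e.coords[e.name == "CA"] for e in ens]
        d_mc = np.array([np.linalg.norm(c[-1] - c[0]) for c in ca])
        rng = np.random.default_rng(12)
        d_direct = np.empty(n)
        for k in range(n):
            b = build_backbone("A" * 10, phi=rng.uniform(-180, 180, 10),
                               psi=rng.uniform(-180, 180, 10), with_cb=False)
            c = b.coords[b.name == "CA"]
            d_direct[k] = np.linalg.norm(c[-1] - c[0])
        assert ks_2samp(d_mc, d_direct).pvalue > 0.01


class TestAttachConformers:
    def _ensemble(self, n):
        m = backbone("AAAA")
        return [m.copy() for _ in range(n)], [
            EnsembleRecord(model_id=f"m{k}") for k in range(n)
        ]

    def _entry(self, label):
        frag = build_backbone("AA", chain="A", start_resid=4, segment="core")
        frag.segment[frag.resid > 4] = "N-glycan"
        return ConformerLibraryEntry(label, frag, anchor_resid=4)

    def test_product_counts_exact(self):
        ens, recs = self._ensemble(7)
        lib = [self._entry(x) for x in ("NG0", "NG1", "NG2")]
        out, orecs = attach_conformers(ens, recs, lib)
        assert len(out) == len(orecs) == 7 * 3
        labels = {r.labels for r in orecs}
        assert labels == {("NG0",), ("NG1",), ("NG2",)}

    def test_identity_fragment_leaves_geometry_unchanged(self):
        ens, recs = self._ensemble(2)
        lib = [self._entry("ID")]
        out, orecs = attach_conformers(ens, recs, lib)
        assert len(out) == 2
        n_host = len(ens[0])
        for e, o in zip(ens, out):
            assert np.allclose(o.coords[:n_host], e.coords, atol=1e-12)
        assert orecs[0].labels == ("ID",)

    def test_fragment_is_rigidly_placed(self):
        from flexsas.models import kabsch

        ens, recs = self._ensemble(1)
        lib = [self._entry("NG0")]
        out, _ = attach_conformers(ens, recs, lib)
        frag = lib[0].fragment
        added = out[0].coords[len(ens[0]):]
        anchor = np.isin(frag.name, ("N", "CA", "C")) & (frag.resid == 4)
        ref = frag.coords[~anchor]
        _, _, rmsd = kabsch(added, ref)
        assert rmsd < 1e-10

    def test_empty_library_rejected(self):
        ens, recs = self._ensemble(1)
        with pytest.raises(ValueError):
            attach_conformers(ens, recs, [])


class TestAddOGlycans:
    def _template(self):
        t = build_backbone("T", with_cb=True)
        sugars = AtomisticModel(
            t.coords[t.name == "CB"] + np.array([[0.0, 0.4, 0.0]]).repeat(3, 0)
            + np.array([[0, 0.0, 0], [0, 0.35, 0], [0, 0.7, 0]]),
            np.array(["C"] * 3, dtype=object),
            np.array(["S1", "S2", "S3"], dtype=object),
            np.full(3, 1, dtype=int),
            np.array(["GLY"] * 3, dtype=object),
            np.array(["A"] * 3, dtype=object),
            np.array(["O-glycan"] * 3, dtype=object),
        )
        return AtomisticModel.concatenate([t, sugars])

    def _host(self):
        h1 = build_backbone("ATATSAT", chain="H1", segment="hinge")
        h2 = build_backbone("ATATSAT", chain="H2", segment="hinge")
        return AtomisticModel.concatenate([h1, h2.translated((0, 3.0, 0))])

    def test_three_sites_two_chains_gives_six_fragments(self):
        host = self._host()
        tpl = self._template()
        sites = [(c, r) for c in ("H1", "H2") for r in (2, 5, 7)]
        out = add_o_glycans(host, sites, tpl, check_clashes=False)
        added = np.count_nonzero(out.segment == "O-glycan")
        assert added == 2 * 3 * 3  # chains x sites x template sugar atoms

    def test_empty_site_list_is_identity(self):
        host = self._host()
        out = add_o_glycans(host, [], self._template())
        assert len(out) == len(host)
        assert np.allclose(out.coords, host.coords)

    def test_non_ser_thr_site_rejected(self):
        host = self._host()
        with pytest.raises(ValueError, match="Ser/Thr"):
            add_o_glycans(host, [("H1", 1)], self._template())

    def test_missing_cb_rejected(self):
        host = build_backbone("ATA", with_cb=False, segment="hinge")
        with pytest.raises(ValueError, match="CB"):
            add_o_glycans(host, [("A", 2)], self._template())


class TestClashCheck:
    def test_close_pair_flags_clash(self):
        m = AtomisticModel(
            np.array([[0, 0, 0], [0.1, 0, 0]]),
            np.array(["C", "C"], dtype=object),
            np.array(["X", "Y"], dtype=object),
            np.array([1, 10]),
            np.array(["DUM", "DUM"], dtype=object),
            np.array(["A", "A"], dtype=object),
            np.array(["core", "core"], dtype=object),
        )
        ok, pairs = clash_check(m, cutoff=0.2, return_pairs=True)
        assert not ok and len(pairs) == 1

    def test_native_backbone_is_clash_free(self):
        m = build_backbone("ACDEFGHIKLMNPQRSTVWY")
        assert clash_check(m, cutoff=0.22)

    def test_toy_antibody_is_clash_free(self, toy_dataset):
        _, model, _, _ = toy_dataset
        assert clash_check(model)

    def test_agrees_with_brute_force_pair_scan(self):
        rng = np.random.default_rng(8)
        for trial in range(5):
            n = 200
            coords = rng.uniform(0, 3, size=(n, 3))
            resid = rng.integers(1, 40, n)
            chain = rng.choice(["A", "B"], n)
            m = AtomisticModel(
                coords,
                np.array(["C"] * n, dtype=object),
                np.array(["X"] * n, dtype=object),
                resid,
                np.array(["DUM"] * n, dtype=object),
                chain.astype(object),
                np.array(["core"] * n, dtype=object),
            )
            _, pairs = clash_check(m, cutoff=0.25, return_pairs=True)
            brute = set()
            for i in range(n):
                for j in range(i + 1, n):
                    if np.linalg.norm(coords[i] - coords[j]) >= 0.25:
                        continue
                    if chain[i] == chain[j] and abs(int(resid[i]) - int(resid[j])) <= 1:
                        continue
                    brute.add((i, j))
            assert {tuple(sorted(p)) for p in pairs} == brute
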