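"""membrane: midplane, local thickness from C2 density peaks, water counts."""

import numpy as np
import pytest

from dnanchor import membrane as mem
from dnanchor import synthetic as syn
from dnanchor.io_model import Atom, Selection, Topology, TrajectorySet, select
from conftest import single_frame


def c2_sheet_traj(upper_z, lower_z, n=50, box=80.0):
    """Two flat C2 sheets at given z, one frame."""
    atoms = []
    coords = []
    rng = np.random.default_rng(5)
    for leaflet, (chain, z) in enumerate([("U", upper_z), ("L", lower_z)]):
        for j in range(n):
            atoms.append(Atom(len(atoms), "C2", "C", "POPC", j + 1, chain))
            coords.append([rng.uniform(0, box), rng.uniform(0, box), z])
    top = Topology(atoms)
    return single_frame(top, np.array(coords), box=(box, box, 120.0))


def axis_dna_system(thin_radius=25.0, delta_z=5.0, n_lipids=600, n_frames=4, box=80.0):
    """Duplex centered in a bilayer thinned inside a wide disk.

    The thinning disk (radius 25 Å) fully contains the near-DNA region
    (15 Å cutoff + <10 Å duplex radius), so the near-DNA C2 population
    sits at +/-14 A while the dominant bulk population stays at +/-19 A.
    """
    top, coords = syn.gen_bdna(syn.BDnaParams())
    coords = coords + np.array([box / 2, box / 2, -48.0])  # axis at box center
    thin = syn.ThinningSpec((box / 2, box / 2), thin_radius, delta_z)
    bil = syn.BilayerParams(n_per_leaflet=n_lipids, z_noise_sd=0.0, box_xy=box, thinning=thin)
    ou = syn.OUParams(stationary_sd=1e-9, dt=1.0, n_frames=n_frames, seed=11)
    traj = syn.gen_anchored_trajectory((top, coords), bil, ou)
    return traj


class TestMidplane:
    def test_symmetric_leaflets(self):
        traj = c2_sheet_traj(19.0, -19.0)
        sel = select(traj.topology, "name C2")
        assert mem.midplane(traj, sel) == pytest.approx(0.0)

    def test_asymmetric_leaflets(self):
        traj = c2_sheet_traj(21.0, -17.0)
        sel = select(traj.topology, "name C2")
        assert mem.midplane(traj, sel) == pytest.approx(2.0)

    def test_noisy_bilayer_midplane_near_zero(self):
        params = syn.BilayerParams(n_per_leaflet=2000, z_noise_sd=1.0)
        top, coords = syn.gen_bilayer(params, seed=13)
        traj = single_frame(top, coords, box=(80.0, 80.0, 120.0))
        sel = select(top, "name C2")
        sem = 1.0 / np.sqrt(2000)  # per-leaflet SEM
        assert abs(mem.midplane(traj, sel)) < 3 * sem

    def test_single_leaflet_rejected(self):
        traj = c2_sheet_traj(19.0, 19.0)
        sel = select(traj.topology, "name C2")
        with pytest.raises(ValueError, match="leaflet"):
            mem.midplane(traj, sel)


class TestLocalThickness:
    def test_noise_free_bilayer_thickness(self, ideal_duplex):
        top, coords = ideal_duplex
        coords = coords + np.array([40.0, 40.0, -48.0])
        bil = syn.BilayerParams(n_per_leaflet=400, z_noise_sd=0.0)
        ou = syn.OUParams(stationary_sd=1e-9, dt=1.0, n_frames=2, seed=1)
        traj = syn.gen_anchored_trajectory((top, coords), bil, ou)
        c2 = select(traj.topology, "name C2")
        dna = select(traj.topology, "chain A or chain B")
        res = mem.local_thickness(traj, c2, dna, discard_ns=0.0)
        assert res.near_dna.thickness == pytest.approx(38.0)
        assert res.bulk.thickness == pytest.approx(38.0)

    def test_thinned_disk_near_dna_thinner_than_bulk(self):
        traj = axis_dna_system()
        c2 = select(traj.topology, "name C2")
        dna = select(traj.topology, "chain A or chain B")
        res = mem.local_thickness(traj, c2, dna, discard_ns=0.0)
        assert res.near_dna.thickness == pytest.approx(28.0)
        assert res.bulk.thickness == pytest.approx(38.0)
        assert res.near_dna.thickness <= res.bulk.thickness

    def test_noisy_peaks_land_near_planes(self):
        bil = syn.BilayerParams(n_per_leaflet=3000, z_noise_sd=1.0)
        top, coords = syn.gen_bilayer(bil, seed=17)
        # a fake one-atom "DNA" on the axis so every lipid is either near or bulk
        dna_top = Topology([Atom(0, "C1'", "C", "DA", 1, "A")])
        full = dna_top.concat(top)
        all_coords = np.vstack([[40.0, 40.0, 0.0], coords])
        traj = single_frame(full, all_coords, box=(80.0, 80.0, 120.0))
        c2 = select(full, "name C2")
        dna = select(full, "chain A")
        res = mem.local_thickness(traj, c2, dna, cutoff=30.0, discard_ns=0.0)
        assert abs(res.near_dna.peak_upper - 19.0) <= 0.5
        assert abs(res.near_dna.peak_lower + 19.0) <= 0.5

    def test_invariant_under_xy_translation_and_z_shift(self):
        traj = axis_dna_system()
        ref = mem.local_thickness(
            traj,
            select(traj.topology, "name C2"),
            select(traj.topology, "chain A or chain B"),
            discard_ns=0.0,
        )
        moved = TrajectorySet(
            traj.topology,
            traj.times,
            traj.boxes,
            traj.coords + np.array([13.0, -7.0, 4.0]),
        )
        res = mem.local_thickness(
            moved,
            select(moved.topology, "name C2"),
            select(moved.topology, "chain A or chain B"),
            discard_ns=0.0,
        )
        assert res.near_dna.thickness == pytest.approx(ref.near_dna.thickness)
        assert res.bulk.thickness == pytest.approx(ref.bulk.thickness)

    def test_all_frames_far_from_dna_rejected(self):
        top, coords = syn.gen_bilayer(syn.BilayerParams(n_per_leaflet=100, z_noise_sd=0.0), seed=2)
        dna_top = Topology([Atom(0, "C1'", "C", "DA", 1, "A")])
        full = dna_top.concat(top)
        all_coords = np.vstack([[40.0, 40.0, 500.0], coords])
        all_coords[1:, :2] = 40.0 + 30.0  # all lipids 30 A away laterally
        traj = single_frame(full, all_coords, box=(1000.0, 1000.0, 1200.0))
        with pytest.raises(ValueError, match="within"):
            mem.local_thickness(
                traj, select(full, "name C2"), select(full, "chain A"),
                cutoff=15.0, discard_ns=0.0,
            )


class TestWaterCount:
    def make_traj_with_water(self, n_inside, n_outside, n_frames=1):
        bil = syn.BilayerParams(n_per_leaflet=100, z_noise_sd=0.0)
        box = (bil.box_xy, bil.box_xy, 118.0)
        water = syn.gen_water_slab(n_inside, n_outside, 10.0, box, seed=4)
        top, coords = syn.gen_bdna(syn.BDnaParams(n_bp=2))
        ou = syn.OUParams(stationary_sd=1e-9, dt=1.0, n_frames=n_frames, seed=3)
        return syn.gen_anchored_trajectory((top, coords), bil, ou, water=water)

    def test_constructed_count_recovered_exactly(self):
        traj = self.make_traj_with_water(37, 500, n_frames=5)
        wc = mem.water_midplane_count(
            traj,
            select(traj.topology, "name O and resname HOH"),
            select(traj.topology, "name C2"),
            discard_ns=0.0,
        )
        assert wc.mean == pytest.approx(37.0)
        assert wc.sd_block == pytest.approx(0.0)
        assert np.all(wc.counts == 37)

    def test_zero_inside(self):
        traj = self.make_traj_with_water(0, 100)
        wc = mem.water_midplane_count(
            traj,
            select(traj.topology, "name O and resname HOH"),
            select(traj.topology, "name C2"),
            discard_ns=0.0,
        )
        assert wc.mean == 0.0

    def test_count_scales_linearly_with_n_inside(self):
        means = []
        for n in (10, 20, 40):
            traj = self.make_traj_with_water(n, 100)
            wc = mem.water_midplane_count(
                traj,
                select(traj.topology, "name O and resname HOH"),
                select(traj.topology, "name C2"),
                discard_ns=0.0,
            )
            means.append(wc.mean)
        assert means == [10.0, 20.0, 40.0]

    def test_block_sd_arithmetic(self):
        # alternating 10/20 counts per 2 ns block: mean 15, block SD 5
        bil = syn.BilayerParams(n_per_leaflet=20, z_noise_sd=0.0)
        top, dup_coords = syn.gen_bdna(syn.BDnaParams(n_bp=2))
        n_frames = 80  # 0.5 ns/frame -> 4 frames per 2 ns block
        ou = syn.OUParams(stationary_sd=1e-9, dt=0.5, n_frames=n_frames, seed=9)
        water = syn.gen_water_slab(20, 0, 10.0, (80.0, 80.0, 118.0), seed=6)
        traj = syn.gen_anchored_trajectory((top, dup_coords), bil, ou, water=water)
        # push 10 of the 20 inside waters out of the slab on odd blocks
        coords = traj.coords.copy()
        w_sel = select(traj.topology, "name O and resname HOH")
        block = (traj.times // 2.0).astype(int)
        odd = block % 2 == 1
        coords[np.ix_(odd, w_sel.array[:10])] += np.array([0.0, 0.0, 40.0])
        traj = TrajectorySet(traj.topology, traj.times, traj.boxes, coords)
        wc = mem.water_midplane_count(
            traj,
            w_sel,
            select(traj.topology, "name C2"),
            discard_ns=0.0,
            sd_block_ns=2.0,
        )
        assert wc.mean == pytest.approx(15.0)
        assert wc.sd_block == pytest.approx(5.0)
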