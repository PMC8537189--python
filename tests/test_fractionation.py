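import pytest
from hypothesis import given
from hypothesis import strategies as stn

from leafdepo import (
    FilterWeighing,
    PMInventory,
    TDSReading,
    ValidationError,
    assemble_inventory,
    density_per_leaf_area,
    mass_proportions,
    species_mean_densities,
)
from leafdepo.fractionation import INVENTORY_CELLS


def make_inventory(masses, area=0.05, batch_id="b1"):
    """masses: 8 values in INVENTORY_CELLS order."""
    return PMInventory(batch_id, dict(zip(INVENTORY_CELLS, masses)), area)


def raw_batch(cell_masses, batch_id="b1", tare=120.0):
    """Raw weighings + TDS implying the given cell masses exactly."""
    weighings, tds = [], []
    for (step, fraction), m in cell_masses.items():
        if fraction in ("DPM", "OPM"):
            tds.append(TDSReading(batch_id, step, m / 0.35, 0.35))
        else:
            pore = {"PM_>10": 10.0, "PM_2.5-10": 2.5, "PM_0.1-2.5": 0.1}[fraction]
            weighings.append(
                FilterWeighing(batch_id, step, pore, (tare,), (tare + m,))
            )
    return weighings, tds


class TestAssembleInventory:
    def test_all_ones(self):
        masses = dict.fromkeys(INVENTORY_CELLS, 1.0)
        w, t = raw_batch(masses)
        inv = assemble_inventory("b1", w, t, leaf_area_m2=0.05)
        assert inv.spm_total == pytest.approx(4.0)
        assert inv.wpm_total == pytest.approx(4.0)

    def test_missing_cell_named(self):
        masses = dict.fromkeys(INVENTORY_CELLS, 1.0)
        w, t = raw_batch(masses)
        w = [x for x in w if not (x.wash_step == "chloroform" and x.pore_um == 2.5)]
        with pytest.raises(ValidationError, match=r"chloroform.*PM_2\.5-10"):
            assemble_inventory("b1", w, t, leaf_area_m2=0.05)

    def test_duplicate_cell_rejected(self):
        masses = dict.fromkeys(INVENTORY_CELLS, 1.0)
        w, t = raw_batch(masses)
        with pytest.raises(ValidationError, match="duplicate"):
            assemble_inventory("b1", w + [w[0]], t, leaf_area_m2=0.05)

    def test_generator_bookkeeping(self, noisefree_study):
        """Noise-free simulated raw measurements reassemble to truth masses."""
        from leafdepo.pipeline import build_inventories

        truth, bundle = noisefree_study
        inventories = build_inventories(bundle)
        areas = bundle.batches.set_index("batch_id")["leaf_area_m2"]
        species_of = bundle.batches.set_index("batch_id")["species_id"]
        for batch_id, inv in list(inventories.items())[:6]:
            for cell in INVENTORY_CELLS:
                expected = truth.density(species_of[batch_id], cell) * areas[batch_id]
                assert inv.masses[cell] == pytest.approx(expected, abs=1e-8)


class TestMassProportions:
    def test_single_nonzero_cell(self):
        masses = [0.0] * 8
        masses[3] = 2.5
        props = mass_proportions(make_inventory(masses))
        assert props[INVENTORY_CELLS[3]] == pytest.approx(100.0)
        assert sum(props.values()) == pytest.approx(100.0)

    def test_equal_cells(self):
        props = mass_proportions(make_inventory([1.0] * 8))
        assert all(v == pytest.approx(12.5) for v in props.values())

    def test_worked_example_spm_share(self):
        # SPM {DPM 2, 0.3, 0.8, 6.9}, WPM {OPM 0.4, 0.3, 0.6, 2.7}: total 14.0
        inv = make_inventory([2.0, 0.3, 0.8, 6.9, 0.4, 0.3, 0.6, 2.7])
        props = mass_proportions(inv)
        spm_share = sum(v for (s, _), v in props.items() if s == "water")
        assert spm_share == pytest.approx(71.4, abs=0.05)

    def test_zero_total_rejected(self):
        with pytest.raises(ValidationError, match="undefined"):
            mass_proportions(make_inventory([0.0] * 8))

    @given(masses=stn.lists(stn.floats(0, 1e3), min_size=8, max_size=8).filter(lambda m: sum(m) > 1e-9))
    def test_sum_to_100(self, masses):
        props = mass_proportions(make_inventory(masses))
        assert sum(props.values()) == pytest.approx(100.0, abs=1e-9)


class TestDensities:
    def test_simple_division(self):
        inv = make_inventory([1.0] * 8, area=0.05)
        dens = density_per_leaf_area(inv)
        assert all(v == pytest.approx(20.0) for v in dens.values())

    def test_area_homogeneity(self):
        masses = [1.0, 2.0, 3.0, 4.0, 0.5, 0.6, 0.7, 0.8]
        d1 = density_per_leaf_area(make_inventory(masses, area=0.05))
        d3 = density_per_leaf_area(make_inventory(masses, area=0.15))
        for cell in INVENTORY_CELLS:
            assert d3[cell] == pytest.approx(d1[cell] / 3.0)

    def test_scaling_masses_and_area_together(self):
        masses = [1.0, 2.0, 3.0, 4.0, 0.5, 0.6, 0.7, 0.8]
        d1 = density_per_leaf_area(make_inventory(masses, area=0.05))
        d2 = density_per_leaf_area(
            make_inventory([m * 2.5 for m in masses], area=0.05 * 2.5)
        )
        for cell in INVENTORY_CELLS:
            assert d2[cell] == pytest.approx(d1[cell])

    def test_species_mean_over_batches(self):
        # batch densities 10/12/14 mg/m^2 in every cell -> species mean 12
        invs = [
            make_inventory([d * 0.05] * 8, area=0.05, batch_id=f"b{i}")
            for i, d in enumerate((10.0, 12.0, 14.0))
        ]
        means = species_mean_densities(invs)
        assert all(v == pytest.approx(12.0) for v in means.values())

    def test_empty_aggregate_rejected(self):
        with pytest.raises(ValidationError):
            species_mean_densities([])
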