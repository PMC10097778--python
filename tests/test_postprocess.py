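"""Averaged quantities, surface loads, DG2 field export."""

import numpy as np
import pytest

from emimech.geometry import (CellGeometrySpec, S2, S4, S6,
                              build_single_cell_mesh, build_tiled_mesh,
                              subdomain_volume)
from emimech.fem import TaylorHoodSpace
from emimech.postprocess import (averaged_component, export_spatial_fields,
                                 read_vtu, surface_load, _load_denominator)
from emimech.solver import SimulationConfig, run_protocol

from conftest import make_affine_state


@pytest.fixture(scope="module")
def ff4_run(small_mesh, small_space, table3_params):
    cfg = SimulationConfig(protocol="FF", magnitude=0.04, n_steps=2,
                           stabilization=25.0)
    return run_protocol(small_mesh, table3_params, cfg, space=small_space)


class TestAveragedComponent:
    def test_reference_state_zero(self, small_space, table3_params):
        st = make_affine_state(small_space, np.eye(3))
        for tensor in ("E", "sigma"):
            for d in ("f0", "s0", "n0"):
                for lab in ("i", "e", 1):
                    v = averaged_component(st, tensor, d, lab,
                                           space=small_space,
                                           params=table3_params)
                    assert abs(v) < 1e-12

    def test_homogeneous_strain_is_exact(self, small_space,
                                         affine_isochoric):
        st = make_affine_state(small_space, affine_isochoric)
        for lab in ("i", "e", 1):
            eff = averaged_component(st, "E", "f0", lab, space=small_space)
            assert eff == pytest.approx((1.1 ** 2 - 1) / 2, rel=1e-12)
            ess = averaged_component(st, "E", "s0", lab, space=small_space)
            assert ess == pytest.approx((1 / 1.1 - 1) / 2, rel=1e-12)

    def test_unknown_label_raises(self, small_space):
        st = make_affine_state(small_space, np.eye(3))
        with pytest.raises(ValueError):
            averaged_component(st, "E", "f0", 42, space=small_space)

    def test_per_cell_decomposition(self, small_spec, affine_isochoric,
                                    table3_params):
        mesh = build_tiled_mesh(small_spec, 2, 1, 1, 20.0)
        space = TaylorHoodSpace(mesh)
        st = make_affine_state(space, affine_isochoric)
        st.gamma = 0.05
        whole = averaged_component(st, "sigma", "f0", "i", space=space,
                                   params=table3_params)
        num = 0.0
        den = 0.0
        for k in (1, 2):
            v = subdomain_volume(mesh, k)
            num += v * averaged_component(st, "sigma", "f0", k, space=space,
                                          params=table3_params)
            den += v
        assert whole == pytest.approx(num / den, rel=1e-12)


class TestSurfaceLoad:
    def test_reference_denominator_is_area(self, small_space):
        st = make_affine_state(small_space, np.eye(3))
        Lx, Ly, Lz = small_space.mesh.box
        assert _load_denominator(st, S2, small_space) == pytest.approx(
            Ly * Lz, rel=1e-12)
        assert _load_denominator(st, S4, small_space) == pytest.approx(
            Lx * Lz, rel=1e-12)

    def test_numerator_equals_reaction(self, ff4_run, small_space):
        """Two routes to the load numerator agree: the surface_load path
        and an explicit dot of the raw residual with the face indicator."""
        states, curve = ff4_run
        st = states[-1]
        load = surface_load(st, S2, np.array([1.0, 0.0, 0.0]),
                            space=small_space)
        nodes = small_space.facet_nodes(S2)
        indicator = np.zeros(small_space.ndof)
        indicator[small_space.u_dofs_of_nodes(nodes, comp=0)] = 1.0
        reaction = float(indicator @ st.raw_residual)
        denom = _load_denominator(st, S2, small_space)
        assert load == pytest.approx(reaction / denom, rel=1e-12)
        assert curve.normal_load[-1] == pytest.approx(load, rel=1e-12)

    def test_non_unit_direction_normalized(self, ff4_run, small_space):
        states, _ = ff4_run
        with pytest.warns(UserWarning):
            doubled = surface_load(states[-1], S2,
                                   np.array([2.0, 0.0, 0.0]),
                                   space=small_space)
        unit = surface_load(states[-1], S2, np.array([1.0, 0.0, 0.0]),
                            space=small_space)
        assert doubled == pytest.approx(unit, rel=1e-12)


class TestSheetNormalSymmetry:
    def test_ss_equals_nn_on_symmetric_padding(self, table3_params):
        """Square-padding fixture: sheet and normal stretch must produce
        identical load curves to round-off (the mesh is built to be
        exactly symmetric under the s<->n swap)."""
        spec = CellGeometrySpec(body_length=30.0, diameter=12.0,
                                pad_sheet=2.0, pad_normal=2.0,
                                fillet_radius=6.0)
        mesh = build_single_cell_mesh(spec, 20.0)
        space = TaylorHoodSpace(mesh)
        loads = {}
        for mode, surf in (("SS", S4), ("NN", S6)):
            cfg = SimulationConfig(protocol=mode, magnitude=0.04, n_steps=2,
                                   stabilization=25.0)
            _, curve = run_protocol(mesh, table3_params, cfg, space=space)
            loads[mode] = curve.normal_load
        scale = max(1e-12, np.abs(loads["SS"]).max())
        assert np.abs(loads["SS"] - loads["NN"]).max() < 1e-8 * scale


class TestSpatialExport:
    def test_reference_fields_zero(self, small_mesh, small_space,
                                   table3_params, tmp_path):
        st = make_affine_state(small_space, np.eye(3))
        st.params = table3_params
        path = tmp_path / "ref.vtu"
        export_spatial_fields(st, small_mesh, path, space=small_space)
        _, _, fields, labels = read_vtu(path)
        assert set(fields) == {"E_ff", "E_ss", "E_nn",
                               "sigma_ff", "sigma_ss", "sigma_nn"}
        for arr in fields.values():
            assert np.abs(arr).max() < 1e-10
        assert np.array_equal(np.sort(np.unique(labels)),
                              np.sort(np.unique(small_mesh.tet_labels)))

    def test_round_trip_reaverages(self, small_mesh, small_space,
                                   table3_params, affine_isochoric,
                                   tmp_path):
        st = make_affine_state(small_space, affine_isochoric)
        st.params = table3_params
        path = tmp_path / "aff.vtu"
        export_spatial_fields(st, small_mesh, path, space=small_space)
        _, conn, fields, labels = read_vtu(path)
        # re-average E_ff over the intracellular subdomain from the DG2
        # nodal values using the element mass matrix
        from emimech.quadrature import tet_rule
        from emimech.fem import p2_shape_values
        bary, w = tet_rule(5)
        N2 = p2_shape_values(bary)
        # VTK node permutation back to local order
        from emimech.postprocess import _VTK_P2_PERM
        inv_perm = np.argsort(_VTK_P2_PERM)
        vals = fields["E_ff"].reshape(-1, 10)[:, inv_perm]
        detJ = small_space.detJ
        mask = labels > 0
        per_el = np.einsum("q,qn,en->e", w, N2, vals)  # int_e f / detJ_e
        integral = per_el[mask] @ detJ[mask]
        volume = detJ[mask].sum() / 6.0
        direct = averaged_component(st, "E", "f0", "i", space=small_space)
        assert integral / volume == pytest.approx(direct, rel=1e-8)


def test_trace_csv(tmp_path, small_mesh, small_space, table3_params):
    from emimech.materials import ActiveTransient
    from emimech.solver import run_contraction
    tr = ActiveTransient()
    states, trace = run_contraction(small_mesh, table3_params, tr, 2,
                                    t_end=tr.t_peak, space=small_space)
    path = tmp_path / "trace.csv"
    trace.to_csv(path)
    import pandas as pd
    df = pd.read_csv(path)
    assert set(df.columns) == {"step_or_time", "quantity", "subdomain",
                               "value"}
    ref = df[df.step_or_time == 0.0]
    assert np.allclose(ref.value, 0.0)
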