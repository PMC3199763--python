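import pytest

from vocbin.models import DeconvolutedPeak, Spectrum
from vocbin.pipeline import run_experiment
from vocbin.registry import BinStore
from vocbin.ri import MarkerHit, default_marker_table, fit_correction_curve
from vocbin.simulate import FixtureConfig, generate_experiment


def make_peak(
    spectrum_pairs,
    sample_id="s1",
    rt=300.0,
    unique_mass=None,
    apex_masses=None,
    sn=100.0,
    purity=0.1,
    height=10_000.0,
):
    spectrum = Spectrum(tuple(sorted(spectrum_pairs)))
    if unique_mass is None:
        unique_mass = spectrum.base_peak_mz
    return DeconvolutedPeak(
        sample_id=sample_id,
        rt=rt,
        spectrum=spectrum,
        unique_mass=unique_mass,
        apex_masses=frozenset(apex_masses or {unique_mass}),
        sn=sn,
        purity=purity,
        unique_ion_height=height,
    )


@pytest.fixture(scope="session")
def marker_table():
    return default_marker_table()


def collinear_marker_hits(markers, slope=1000.0):
    """Marker hits whose rt is exactly affine in RI: rt = ri / slope."""
    hits = []
    for m in markers:
        peak = make_peak(
            [(mz, i) for mz, i in m.reference_spectrum.peaks],
            rt=m.ri_fame / slope,
            unique_mass=74,
        )
        hits.append(MarkerHit(marker=m, peak=peak, similarity=1000))
    return hits


@pytest.fixture(scope="session")
def collinear_curve(marker_table):
    return fit_correction_curve(collinear_marker_hits(marker_table), marker_table)


@pytest.fixture(scope="session")
def default_experiment(tmp_path_factory):
    """One default synthetic experiment with raw files, shared by e2e tests."""
    out = tmp_path_factory.mktemp("experiment")
    cfg = FixtureConfig(seed=11)
    design, tables, truth = generate_experiment(cfg, out, write_raw=True)
    return {"cfg": cfg, "design": design, "tables": tables, "truth": truth, "dir": out}


@pytest.fixture(scope="session")
def default_run(default_experiment, tmp_path_factory):
    """Full pipeline run on the default experiment (fresh in-memory store)."""
    out = tmp_path_factory.mktemp("run_out")
    result = run_experiment(
        default_experiment["design"],
        default_experiment["tables"],
        BinStore(),
        out_dir=out,
    )
    return {**default_experiment, "result": result, "out": out}


def map_bins_to_compounds(store, truth, window=2000.0):
    """Associate each created Bin with the ground-truth compound at its RI."""
    comp_ri = {}
    for o in truth.occurrences:
        comp_ri[o.compound] = o.true_ri
    mapping = {}
    for b in store.bins():
        comp = min(comp_ri, key=lambda c: abs(comp_ri[c] - b.ri))
        mapping[b.bin_id] = comp if abs(comp_ri[comp] - b.ri) <= window else None
    return mapping, comp_ri
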