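import numpy as np
import pytest

from pmfkit.digest import DigestParams, TheoreticalFingerprint, TheoreticalPeptide, digest
from pmfkit.pmf_match import (
    AmbiguityNote,
    PeakList,
    PeakListFormatError,
    ToleranceUnit,
    ambiguity_scan,
    calibrate,
    identify,
    match,
    read_peaklist,
    write_peaklist_mgf,
    write_peaklist_tsv,
)
from pmfkit.seqmodel import ProteinRecord, Proteoform
from pmfkit.synthetic_data import SimConfig, simulate_proteome, simulate_spot

from conftest import make_record


def make_peaklist(mzs, spot_id="s", calibrated=True):
    return PeakList(
        spot_id=spot_id,
        peaks=tuple((mz, None) for mz in sorted(mzs)),
        calibrated=calibrated,
    )


def make_fingerprint(masses, chain_len=None):
    """Hand-built fingerprint with one single-residue peptide per mass."""
    n = chain_len or len(masses)
    rec = ProteinRecord(id="dummy", sequence="G" * max(n, 1))
    peps = tuple(
        TheoreticalPeptide(
            span=(i + 1, i + 1), sequence="G", missed=0, mod_state=(), mh_mono=m
        )
        for i, m in enumerate(masses)
    )
    return TheoreticalFingerprint(
        form=Proteoform(rec), peptides=peps, params=DigestParams()
    )


class TestReadPeaklist:
    def test_tsv_sorted(self, tmp_path):
        f = tmp_path / "a.tsv"
        f.write_text("1000.0\n842.51\n")
        pl = read_peaklist(f)
        assert pl.mz == (842.51, 1000.0)
        assert pl.spot_id == "a"

    def test_tsv_with_intensity(self, tmp_path):
        f = tmp_path / "a.tsv"
        f.write_text("842.51\t100\n1000.0\t5\n")
        assert pl_peaks(read_peaklist(f)) == [(842.51, 100.0), (1000.0, 5.0)]

    def test_non_numeric_line_reported(self, tmp_path):
        f = tmp_path / "bad.tsv"
        f.write_text("abc\n")
        with pytest.raises(PeakListFormatError, match="line 1"):
            read_peaklist(f)

    def test_duplicates_collapsed_max_intensity(self, tmp_path):
        f = tmp_path / "a.tsv"
        f.write_text("842.51\t3\n842.51\t9\n")
        assert pl_peaks(read_peaklist(f)) == [(842.51, 9.0)]

    def test_mgf_block(self, tmp_path):
        f = tmp_path / "a.mgf"
        f.write_text(
            "BEGIN IONS\nTITLE=spot7\nPEPMASS=1000\n842.51 12\n2211.10 8\nEND IONS\n"
        )
        pl = read_peaklist(f)
        assert pl.spot_id == "spot7"
        assert pl.mz == (842.51, 2211.10)

    def test_mgf_pepmass_only_warns_empty(self, tmp_path, caplog):
        f = tmp_path / "a.mgf"
        f.write_text("BEGIN IONS\nPEPMASS=1000\nEND IONS\n")
        with caplog.at_level("WARNING"):
            pl = read_peaklist(f)
        assert len(pl) == 0
        assert "empty" in caplog.text.lower()

    def test_roundtrip_tsv_and_mgf(self, tmp_path):
        pl = make_peaklist([500.5, 1200.25, 3999.0])
        t, m = tmp_path / "x.tsv", tmp_path / "x.mgf"
        write_peaklist_tsv(pl, t)
        write_peaklist_mgf(pl, m)
        assert read_peaklist(t).mz == pytest.approx(pl.mz)
        assert read_peaklist(m).mz == pytest.approx(pl.mz)


def pl_peaks(pl):
    return [(mz, i) for mz, i in pl.peaks]


class TestPeakListInvariants:
    def test_rejects_unsorted(self):
        with pytest.raises(ValueError):
            PeakList(spot_id="s", peaks=((1000.0, None), (842.0, None)))

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            PeakList(spot_id="s", peaks=((0.0, None),))


class TestCalibrate:
    REFS = ((842.00, 842.51), (2211.00, 2211.10))

    def test_anchor_maps_exactly(self):
        pl = calibrate(make_peaklist([842.00]), self.REFS)
        assert pl.mz[0] == pytest.approx(842.51, abs=1e-9)
        assert pl.calibrated

    def test_identity_refs(self):
        refs = ((842.51, 842.51), (2211.10, 2211.10))
        pl0 = make_peaklist([600.0, 1500.0])
        pl = calibrate(pl0, refs)
        assert pl.mz == pytest.approx(pl0.mz, abs=1e-12)

    def test_midpoint_property(self):
        # affine: midpoint of observed anchors maps to midpoint of true anchors
        mid_obs = (842.00 + 2211.00) / 2
        mid_true = (842.51 + 2211.10) / 2
        pl = calibrate(make_peaklist([mid_obs]), self.REFS)
        assert pl.mz[0] == pytest.approx(mid_true, abs=1e-9)
        # independent line fit oracle
        slope, intercept = np.polyfit([842.00, 2211.00], [842.51, 2211.10], 1)
        assert pl.mz[0] == pytest.approx(slope * mid_obs + intercept, abs=1e-9)

    def test_degenerate_raises(self):
        with pytest.raises(ValueError):
            calibrate(make_peaklist([900.0]), ((842.0, 842.5), (842.0, 843.0)))

    def test_invertible(self):
        pl0 = make_peaklist([600.0, 1500.0, 3000.0])
        fwd = calibrate(pl0, self.REFS)
        inv_refs = ((842.51, 842.00), (2211.10, 2211.00))
        back = calibrate(fwd, inv_refs)
        assert back.mz == pytest.approx(pl0.mz, abs=1e-9)


class TestMatch:
    def test_within_tolerance(self):
        pl = make_peaklist([1000.010])
        fp = make_fingerprint([1000.000])
        mr = match(pl, fp, tol=50.0, tol_unit=ToleranceUnit.PPM)
        assert mr.matched_count == 1
        assert mr.assignments[0][2] == pytest.approx(10.0, abs=0.01)  # ppm

    def test_outside_tolerance(self):
        pl = make_peaklist([1000.010])
        fp = make_fingerprint([1000.000])
        mr = match(pl, fp, tol=5.0, tol_unit=ToleranceUnit.PPM)
        assert mr.matched_count == 0

    def test_da_unit(self):
        pl = make_peaklist([1000.04])
        fp = make_fingerprint([1000.000])
        assert match(pl, fp, tol=0.05, tol_unit=ToleranceUnit.DA).matched_count == 1
        assert match(pl, fp, tol=0.03, tol_unit=ToleranceUnit.DA).matched_count == 0

    def test_coverage_union(self):
        # chain of length 20, matched spans (1,5) and (3,10) -> 50%
        rec = ProteinRecord(id="p", sequence="G" * 20)
        peps = (
            TheoreticalPeptide((1, 5), "GGGGG", 0, (), 600.0),
            TheoreticalPeptide((3, 10), "GGGGGGGG", 1, (), 900.0),
        )
        fp = TheoreticalFingerprint(Proteoform(rec), peps, DigestParams())
        pl = make_peaklist([600.0, 900.0])
        mr = match(pl, fp, tol=0.1, tol_unit=ToleranceUnit.DA)
        assert mr.coverage_pct == pytest.approx(50.0)
        assert mr.coverage_display == 50

    def test_one_to_one(self):
        pl = make_peaklist([1000.0, 1000.001])
        fp = make_fingerprint([1000.0])
        mr = match(pl, fp, tol=0.1, tol_unit=ToleranceUnit.DA)
        assert mr.matched_count == 1

    def test_requires_calibration_flag(self):
        pl = make_peaklist([1000.0], calibrated=False)
        fp = make_fingerprint([1000.0])
        with pytest.raises(ValueError, match="calibrated"):
            match(pl, fp, tol=0.1, tol_unit=ToleranceUnit.DA)
        assert match(
            pl, fp, tol=0.1, tol_unit=ToleranceUnit.DA, accept_uncalibrated=True
        ).matched_count == 1

    def test_bad_tolerance(self):
        with pytest.raises(ValueError):
            match(make_peaklist([1000.0]), make_fingerprint([1000.0]), tol=0.0)


def optimal_matching_size(peaks, masses, tol_da):
    """Exhaustive maximum-bipartite-matching oracle (augmenting paths)."""
    edges = {
        i: [j for j, m in enumerate(masses) if abs(p - m) <= tol_da]
        for i, p in enumerate(peaks)
    }
    owner: dict[int, int] = {}

    def try_assign(i, seen):
        for j in edges[i]:
            if j in seen:
                continue
            seen.add(j)
            if j not in owner or try_assign(owner[j], seen):
                owner[j] = i
                return True
        return False

    size = 0
    for i in edges:
        if try_assign(i, set()):
            size += 1
    return size


class TestGreedyVsOptimal:
    @pytest.mark.parametrize("seed", range(60))
    def test_realistic_instances(self, seed):
        """Greedy equals the exhaustive optimum on simulator-like instances."""
        rng = np.random.default_rng(seed)
        n_theory = int(rng.integers(3, 9))
        masses = np.sort(rng.uniform(500, 4000, n_theory))
        keep = rng.random(n_theory) < 0.7
        peaks = masses[keep] * (1 + rng.normal(0, 10e-6, keep.sum()))
        n_noise = int(rng.integers(0, 4))
        peaks = np.sort(
            np.concatenate([peaks, rng.uniform(500, 4000, n_noise)])
        )[:8]
        peaks = np.unique(peaks)
        if peaks.size == 0:
            return
        tol_da = 0.2
        fp = make_fingerprint(list(masses))
        pl = make_peaklist(list(peaks))
        mr = match(pl, fp, tol=tol_da, tol_unit=ToleranceUnit.DA)
        assert mr.matched_count == optimal_matching_size(peaks, masses, tol_da)

    @pytest.mark.parametrize("seed", range(30))
    def test_peak_removal_monotonicity(self, seed):
        rng = np.random.default_rng(1000 + seed)
        masses = np.sort(rng.uniform(500, 4000, 10))
        peaks = np.sort(rng.uniform(500, 4000, 8))
        fp = make_fingerprint(list(masses))
        full = match(make_peaklist(list(peaks)), fp, tol=5.0, tol_unit=ToleranceUnit.DA)
        drop = int(rng.integers(0, len(peaks)))
        reduced_peaks = np.delete(peaks, drop)
        reduced = match(
            make_peaklist(list(reduced_peaks)), fp, tol=5.0, tol_unit=ToleranceUnit.DA
        )
        assert reduced.matched_count <= full.matched_count

    def test_matched_count_bounded(self):
        fp = make_fingerprint([1000.0, 1001.0])
        pl = make_peaklist([1000.0, 1000.5, 1001.0])
        mr = match(pl, fp, tol=5.0, tol_unit=ToleranceUnit.DA)
        assert mr.matched_count <= min(len(pl), len(fp.peptides))


class TestIdentify:
    def setup_candidates(self, seed=3, n=2, wide=True):
        cfg = SimConfig(seed=seed, n_proteins=n, error_ppm_sd=0.0)
        records, _ = simulate_proteome(cfg)
        params = (
            DigestParams(min_len=1, mass_window=(1.0, 1e7)) if wide else DigestParams()
        )
        return records, params

    def test_empty_peaklist(self):
        records, params = self.setup_candidates()
        candidates = [digest(Proteoform(r), params) for r in records]
        pl = PeakList(spot_id="s", peaks=(), calibrated=True)
        ident = identify(pl, candidates)
        assert ident.accepted == ()
        assert not ident.mixture_flag

    def test_true_protein_ranked_first_full_coverage(self):
        records, params = self.setup_candidates()
        cfg = SimConfig(seed=3, n_proteins=2, error_ppm_sd=0.0)
        rng = np.random.default_rng(11)
        pl, _, _ = simulate_spot([Proteoform(records[0])], cfg, "s", rng, params)
        candidates = [digest(Proteoform(r), params) for r in records]
        ident = identify(pl, candidates, tol=10.0)
        top = ident.ranked[0]
        assert top.fingerprint.form.protein.id == records[0].id
        assert top.coverage_pct == pytest.approx(100.0)

    def test_mixture_flag(self):
        records, params = self.setup_candidates()
        cfg = SimConfig(seed=3, n_proteins=2, error_ppm_sd=0.0)
        rng = np.random.default_rng(12)
        pl, _, _ = simulate_spot(
            [Proteoform(records[0]), Proteoform(records[1])], cfg, "mix", rng, params
        )
        candidates = [digest(Proteoform(r), params) for r in records]
        ident = identify(pl, candidates, tol=10.0)
        assert ident.mixture_flag
        assert len(ident.accepted) == 2

    def test_empty_candidates_raise(self):
        with pytest.raises(ValueError):
            identify(make_peaklist([1000.0]), [])

    def test_deterministic_tiebreak(self):
        a = make_fingerprint([1000.0])
        b = make_fingerprint([1000.0])
        object.__setattr__(a.form.protein, "accession", "AAA")
        object.__setattr__(b.form.protein, "accession", "BBB")
        pl = make_peaklist([1000.0])
        ident = identify(pl, [b, a], tol=0.1, tol_unit=ToleranceUnit.DA, min_matched=1)
        accs = [mr.fingerprint.form.protein.accession for mr in ident.ranked]
        assert accs == ["AAA", "BBB"]


class TestAmbiguityScan:
    def test_well_separated_empty(self):
        fp = make_fingerprint([1000.0, 2000.0])
        pl = make_peaklist([1000.0])
        ident = identify(pl, [fp], tol=0.1, tol_unit=ToleranceUnit.DA, min_matched=1)
        assert ambiguity_scan(ident, tol=0.15) == []

    def test_duplicate_candidates_note_every_matched_peak(self):
        a = make_fingerprint([1000.0, 2000.0])
        b = make_fingerprint([1000.0, 2000.0])
        pl = make_peaklist([1000.0, 2000.0])
        ident = identify(pl, [a, b], tol=0.1, tol_unit=ToleranceUnit.DA, min_matched=1)
        notes = ambiguity_scan(ident, tol=0.15)
        assert len(notes) == 2  # one note per matched peak, deduplicated
        assert all(isinstance(n, AmbiguityNote) for n in notes)

    def test_near_isobaric_pair_reported(self):
        a = make_fingerprint([1498.7424])
        b = make_fingerprint([1498.6227])
        pl = make_peaklist([1498.74])
        ident = identify(pl, [a, b], tol=0.05, tol_unit=ToleranceUnit.DA, min_matched=1)
        notes = ambiguity_scan(ident, tol=0.15)
        assert len(notes) == 1
        assert notes[0].delta_da == pytest.approx(0.1197, abs=1e-3)
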