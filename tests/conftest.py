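from types import SimpleNamespace

import pytest

import bactsig as bs


@pytest.fixture(scope="session")
def default_sim():
    """The shipped default synthetic experiment: 48 clones in 5 groups, two
    planted signatures, 4:1 transcribed-strand bias on the glycine-like one."""
    cfg = bs.default_config(seed=7)
    genome, genes = bs.generate_genome(cfg)
    sigs = bs.default_signatures()
    result = bs.simulate_clones(genome, genes, sigs, cfg)
    return SimpleNamespace(
        config=cfg, genome=genome, genes=genes, signatures=sigs, result=result
    )


@pytest.fixture(scope="session")
def sim_vcfs(default_sim, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("clone_vcfs")
    paths = bs.write_clone_vcfs(default_sim.result, outdir)
    snv_lists = {cid: bs.read_snvs(p, cid) for cid, p in paths.items()}
    return SimpleNamespace(paths=paths, snv_lists=snv_lists)


@pytest.fixture(scope="session")
def catalog96(default_sim, sim_vcfs):
    return bs.build_catalog(sim_vcfs.snv_lists, default_sim.genome)


@pytest.fixture(scope="session")
def stranded_catalog(default_sim, sim_vcfs):
    return bs.build_catalog(
        sim_vcfs.snv_lists,
        default_sim.genome,
        stranded=True,
        annotation=default_sim.genes,
    )


@pytest.fixture(scope="session")
def extraction(catalog96):
    """Bootstrap-NMF model selection on the default experiment (shared by
    the signature-recovery tests; moderate bootstrap settings)."""
    return bs.select_k(
        catalog96, 1, 4, n_bootstraps=30, n_restarts=3, max_iter=3000,
        tol=1e-7, seed=11,
    )


@pytest.fixture()
def vcf_writer(tmp_path):
    """Write a minimal VCFv4.2 file from (pos, ref, alt, filter) tuples."""

    def _write(records, name="sample.vcf", chrom="chr1", contig_len=100000):
        path = tmp_path / name
        lines = [
            "##fileformat=VCFv4.2",
            f"##contig=<ID={chrom},length={contig_len}>",
            '##FILTER=<ID=PASS,Description="All filters passed">',
            '##FILTER=<ID=q10,Description="Low quality">',
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
        ]
        for pos, ref, alt, filt in records:
            lines.append(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\t{filt}\t.")
        path.write_text("\n".join(lines) + "\n")
        return path

    return _write
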