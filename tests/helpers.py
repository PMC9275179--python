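"""Shared builders for pipeline-level tests."""

from methylga.ilga import IlgaConfig
from methylga.methyl_data import write_beta_csv, write_labels_csv
from methylga.olga import OlgaConfig
from methylga.pipeline import RunConfig
from methylga.synthetic import CohortSpec, generate_cohort


def write_cohort_files(tmp_path, seed=7):
    """Split a 6-class synthetic cohort (3 cancer types x malignant/benign)
    into per-type matrix + label CSVs, as the pipeline expects."""
    spec = CohortSpec(
        n_samples_per_class=12,
        class_labels=(("BRCA", True), ("BRCA", False), ("OV", True),
                      ("OV", False), ("STAD", True), ("STAD", False)),
        n_informative_loci=40, n_noise_loci=160,
        informative_separation=0.9, noise_concentration=50.0, seed=seed)
    matrix, truth = generate_cohort(spec)
    cohorts = {}
    for name in ("BRCA", "OV", "STAD"):
        idx = [i for i, s in enumerate(matrix.sample_ids)
               if matrix.labels.loc[s, "cancer_type"] == name]
        sub = matrix.select_samples(idx)
        mpath = tmp_path / f"{name}.matrix.csv"
        lpath = tmp_path / f"{name}.labels.csv"
        write_beta_csv(sub, mpath)
        write_labels_csv(sub.labels, lpath)
        cohorts[name] = {"matrix": str(mpath), "labels": str(lpath)}
    return cohorts, truth


def small_config(tmp_path, cohorts, outdir="run", seed=5):
    return RunConfig(
        cohorts=cohorts,
        platform="custom", n_loci=200, rejection_threshold=0.10,
        master_seed=seed, output_dir=str(tmp_path / outdir),
        olga=OlgaConfig(population_size=6, generations=2, elite_count=1,
                        ilga_config=IlgaConfig(population_size=8,
                                               generations=10)),
        binary_hidden=(32,), pan_hidden=(32, 16), epochs=40)
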