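[
  {
    "id": "c1_subjects_dims",
    "prompt_text": "I have a tab separated file called \"subjects.txt\". Read it and tell me how many rows and columns it has.",
    "data_files": ["subjects.txt"],
    "components": ["read_file"]
  },
  {
    "id": "c1_expression_genes",
    "prompt_text": "I have the following gene expression data, \"leukemiaExp.txt\". The file is tab separated. The table has gene names on the first column. Read the file and print how many genes it contains.",
    "data_files": ["leukemiaExp.txt"],
    "components": ["read_file"]
  },
  {
    "id": "c1_samplesheet_head",
    "prompt_text": "Read the tab separated file \"samplesheet.txt\" and show me its first five rows.",
    "data_files": ["samplesheet.txt"],
    "components": ["read_file"]
  },
  {
    "id": "c1_expression_columns",
    "prompt_text": "I have a tab separated expression table called \"expressionB.txt\". Read it and list the column names.",
    "data_files": ["expressionB.txt"],
    "components": ["read_file"]
  },
  {
    "id": "c2_filter_age",
    "prompt_text": "Read the tab separated file \"subjects.txt\". Keep only the rows where the age column is greater than 50 and report how many rows remain.",
    "data_files": ["subjects.txt"],
    "components": ["read_file", "wrangle"]
  },
  {
    "id": "c2_transpose",
    "prompt_text": "I have gene expression data in \"leukemiaExp.txt\", tab separated, genes in rows and samples in columns. Read it, transpose the matrix so that rows are samples, and print the resulting dimensions.",
    "data_files": ["leukemiaExp.txt"],
    "components": ["read_file", "wrangle"]
  },
  {
    "id": "c2_age_histogram",
    "prompt_text": "Read the tab separated file \"subjects.txt\" and plot a histogram of the age column. Save the plot to a file.",
    "data_files": ["subjects.txt"],
    "components": ["read_file", "visualize"]
  },
  {
    "id": "c2_group_ttest",
    "prompt_text": "Read the tab separated file \"subjects.txt\" and perform a t-test comparing age between the two largest treatment groups. Report the p-value.",
    "data_files": ["subjects.txt"],
    "components": ["read_file", "ml_stats"]
  },
  {
    "id": "c3_variance_histogram",
    "prompt_text": "I have gene expression data in \"leukemiaExp.txt\", tab separated, with gene names in the first column. Read it, compute the variance of each gene across samples, and plot a histogram of the variances. Save the figure to a file.",
    "data_files": ["leukemiaExp.txt"],
    "components": ["read_file", "wrangle", "visualize"]
  },
  {
    "id": "c3_log_pca",
    "prompt_text": "Read the tab separated expression table \"expressionB.txt\" (genes in rows, samples in columns). Log-transform the values, run a principal component analysis on the samples, and report the variance explained by the first two components.",
    "data_files": ["expressionB.txt"],
    "components": ["read_file", "wrangle", "ml_stats"]
  },
  {
    "id": "c3_top_genes_boxplot",
    "prompt_text": "Read the tab separated file \"leukemiaExp.txt\" with genes in rows. Select the 20 most variable genes and draw a boxplot of their expression values per sample. Save the plot to a file.",
    "data_files": ["leukemiaExp.txt"],
    "components": ["read_file", "wrangle", "visualize"]
  },
  {
    "id": "c3_treatment_association",
    "prompt_text": "Read the tab separated file \"subjects.txt\". Drop any incomplete rows, then test whether the treatment column is associated with the subject column categories using a chi-square test, and report the p-value.",
    "data_files": ["subjects.txt"],
    "components": ["read_file", "wrangle", "ml_stats"]
  },
  {
    "id": "c4_cluster_leukemia",
    "prompt_text": "I have the following gene expression data, \"leukemiaExp.txt\". The file is tab separated. The table has gene names on the first column. Each row is a gene and each column is a distinct sample. Filter genes based on their variability so we retain the most variable top 20 genes. Based on these variable genes cluster the samples, extract cluster specific genes for each cluster, and draw a heatmap of the result.",
    "data_files": ["leukemiaExp.txt"],
    "components": ["read_file", "wrangle", "visualize", "ml_stats"]
  },
  {
    "id": "c4_pca_scatter",
    "prompt_text": "Read the tab separated expression table \"expressionB.txt\". Normalize each gene to zero mean and unit variance, run a principal component analysis on the samples, cluster the samples with k-means (k = 2), and save a scatter plot of the first two components colored by cluster.",
    "data_files": ["expressionB.txt"],
    "components": ["read_file", "wrangle", "visualize", "ml_stats"]
  },
  {
    "id": "c4_kmeans_silhouette",
    "prompt_text": "Read the tab separated file \"leukemiaExp.txt\" (genes in rows, samples in columns). Scale the data, cluster the samples with k-means for k = 3, compute the silhouette score, and save a plot of the clustered samples.",
    "data_files": ["leukemiaExp.txt"],
    "components": ["read_file", "wrangle", "visualize", "ml_stats"]
  },
  {
    "id": "c4_volcano",
    "prompt_text": "Read the tab separated expression table \"expressionB.txt\". Split the samples into two equal groups, run a t-test per gene between the groups, and save a volcano plot of the log fold change against the p-values.",
    "data_files": ["expressionB.txt"],
    "components": ["read_file", "wrangle", "visualize", "ml_stats"]
  },
  {
    "id": "c5_annotated_heatmap",
    "prompt_text": "I have gene expression data in \"leukemiaExp.txt\" and subject annotations in \"subjects.txt\", both tab separated. Read both files, keep the most variable genes, cluster the samples, and draw a heatmap of the clustered expression annotated with the treatment column from the annotations.",
    "data_files": ["leukemiaExp.txt", "subjects.txt"],
    "components": ["read_file", "wrangle", "visualize", "ml_stats", "multi_dataset"]
  },
  {
    "id": "c5_combine_pca",
    "prompt_text": "I have two tab separated gene expression tables, \"leukemiaExp.txt\" and \"expressionB.txt\", each with genes in rows and samples in columns. Read both, keep the genes common to both tables, combine the samples into one matrix, scale it, run a principal component analysis, and save a scatter plot of the first two components colored by dataset of origin.",
    "data_files": ["leukemiaExp.txt", "expressionB.txt"],
    "components": ["read_file", "wrangle", "visualize", "ml_stats", "multi_dataset"]
  },
  {
    "id": "c5_join_model",
    "prompt_text": "Read the tab separated files \"subjects.txt\" and \"samplesheet.txt\". Join them on their categorical group columns, drop incomplete rows, fit a linear model of age against condition, and save a plot of the fitted group means with error bars.",
    "data_files": ["subjects.txt", "samplesheet.txt"],
    "components": ["read_file", "wrangle", "visualize", "ml_stats", "multi_dataset"]
  },
  {
    "id": "c5_expression_age",
    "prompt_text": "I have an expression table \"expressionB.txt\" and subject annotations \"subjects.txt\", both tab separated. Read both files, match samples to subjects by position, correlate each gene's expression with age, and save a scatter plot of the most correlated gene against age.",
    "data_files": ["expressionB.txt", "subjects.txt"],
    "components": ["read_file", "wrangle", "visualize", "ml_stats", "multi_dataset"]
  }
]
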