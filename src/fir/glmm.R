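# Binomial GLMM backend: lme4 fit, car::Anova type-II Wald chi-squares,
# emmeans post-hoc pre/post odds ratios (CIs on the log-odds scale,
# back-transformed).  Called by fir.behavior_stats via Rscript.
#
# usage: Rscript glmm.R <counts.csv> <out.json> <posthoc 0|1>
# counts.csv columns: replicate, participant, cls, time (pre|post),
#                     fusion, total [, stimulus]

suppressMessages({
  library(lme4)
  library(car)
  library(jsonlite)
})

args <- commandArgs(trailingOnly = TRUE)
counts_path <- args[1]
out_path <- args[2]
want_posthoc <- args[3] == "1"
if (want_posthoc) suppressMessages(library(emmeans))

d <- read.csv(counts_path, stringsAsFactors = FALSE)
d$time <- factor(d$time, levels = c("pre", "post"))
d$cls <- factor(d$cls)
has_stimulus <- "stimulus" %in% names(d) && length(unique(d$stimulus)) > 1

fit_one <- function(di) {
  form <- cbind(fusion, total - fusion) ~ time * cls + (1 | participant)
  if (has_stimulus) {
    form <- cbind(fusion, total - fusion) ~ time * cls + (1 | participant) + (1 | stimulus)
  }
  m <- tryCatch(
    suppressMessages(suppressWarnings(glmer(form, data = di, family = binomial))),
    error = function(e) NULL
  )
  singular <- if (is.null(m)) TRUE else isSingular(m, tol = 1e-4)
  if (!is.null(m) && singular && has_stimulus) {
    # fall back to the intercept-only (participant) random structure
    m <- tryCatch(
      suppressMessages(suppressWarnings(glmer(
        cbind(fusion, total - fusion) ~ time * cls + (1 | participant),
        data = di, family = binomial
      ))),
      error = function(e) NULL
    )
    singular <- if (is.null(m)) TRUE else isSingular(m, tol = 1e-4)
  }
  if (is.null(m)) {
    # the GLMM is unfittable (e.g. degenerate random-effect structure):
    # drop to the fixed-effects binomial GLM, the zero-variance limit
    m <- glm(cbind(fusion, total - fusion) ~ time * cls, data = di, family = binomial)
    converged <- m$converged
  } else {
    conv <- m@optinfo$conv$lme4
    converged <- is.null(conv$code) || conv$code >= 0
  }
  a <- car::Anova(m, type = 2)
  names(a)[grep("Chisq$", names(a))[1]] <- "Chisq"
  fe <- if (inherits(m, "merMod")) fixef(m) else coef(m)
  out <- list(
    singular = singular,
    converged = converged,
    anova = data.frame(
      term = rownames(a),
      chisq = a$Chisq,
      df = a$Df,
      p = a$`Pr(>Chisq)`,
      stringsAsFactors = FALSE
    ),
    coef_names = names(fe),
    coef = as.numeric(fe),
    vcov = as.matrix(vcov(m))
  )
  if (want_posthoc) {
    emm <- emmeans(m, ~ time | cls)
    pr <- summary(pairs(emm, reverse = TRUE), infer = c(TRUE, TRUE), type = "response")
    fin <- function(x) ifelse(is.finite(x), x, NA_real_)  # JSON has no Inf
    out$posthoc <- data.frame(
      cls = as.character(pr$cls),
      odds_ratio = fin(pr$odds.ratio),
      ci_low = fin(pr$asymp.LCL),
      ci_high = fin(pr$asymp.UCL),
      z = fin(pr$z.ratio),
      p = fin(pr$p.value),
      stringsAsFactors = FALSE
    )
  }
  out
}

res <- list()
for (rep_id in unique(d$replicate)) {
  di <- d[d$replicate == rep_id, ]
  res[[as.character(rep_id)]] <- tryCatch(
    fit_one(di),
    error = function(e) list(error = conditionMessage(e))
  )
}

writeLines(toJSON(res, digits = 12, auto_unbox = TRUE, na = "null"), out_path)
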