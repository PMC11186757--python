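"""Controlled unit vocabulary for measurement tables.

Internal canonical units are g P m-2 for pools and g P m-2 yr-1 for fluxes;
every unit conversion happens exactly once, at ingest (see ``assemble``).
"""

MG_P_PER_G = "mg_P_per_g"
MG_P_PER_KG = "mg_P_per_kg"
G_PER_M2 = "g_per_m2"
G_PER_M2_PER_INTERVAL = "g_per_m2_per_interval"
G_PER_CM3 = "g_per_cm3"
MG_P_PER_L = "mg_P_per_L"
G_C_PER_M2_PER_YR = "g_C_per_m2_per_yr"
G_C_PER_KG = "g_C_per_kg"

VOCABULARY = frozenset(
    {
        MG_P_PER_G,
        MG_P_PER_KG,
        G_PER_M2,
        G_PER_M2_PER_INTERVAL,
        G_PER_CM3,
        MG_P_PER_L,
        G_C_PER_M2_PER_YR,
        G_C_PER_KG,
    }
)

#: fixed column order shared by every measurement CSV
COLUMNS = [
    "plot_id",
    "treatment",
    "date",
    "component",
    "depth_top_cm",
    "depth_bottom_cm",
    "subrep",
    "variable",
    "value",
    "unit",
]
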