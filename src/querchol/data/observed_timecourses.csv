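treatment,species,time_min,replicate,value,sd,unit,source
nitrogen,quercetin,0,1,100.0,,percent_of_initial,quercetin-timecourse
nitrogen,quercetin,10,1,92.1,,percent_of_initial,quercetin-timecourse
nitrogen,quercetin,30,1,82.8,,percent_of_initial,quercetin-timecourse
nitrogen,quercetin,60,1,71.4,,percent_of_initial,quercetin-timecourse
nitrogen,quercetin,120,1,66.1,,percent_of_initial,quercetin-timecourse
oxygen,quercetin,0,1,100.0,,percent_of_initial,quercetin-timecourse
oxygen,quercetin,10,1,79.6,,percent_of_initial,quercetin-timecourse
oxygen,quercetin,30,1,71.8,,percent_of_initial,quercetin-timecourse
oxygen,quercetin,60,1,35.2,,percent_of_initial,quercetin-timecourse
oxygen,quercetin,120,1,17.6,,percent_of_initial,quercetin-timecourse
oxygen_cholesterol,quercetin,0,1,100.0,,percent_of_initial,quercetin-timecourse
oxygen_cholesterol,quercetin,10,1,10.9,,percent_of_initial,quercetin-timecourse
oxygen_cholesterol,quercetin,30,1,5.9,,percent_of_initial,quercetin-timecourse
control_no_quercetin,total_COPs,0,1,0.08,0.00,percent_of_initial,total-cops-table
control_no_quercetin,total_COPs,5,1,0.18,0.01,percent_of_initial,total-cops-table
control_no_quercetin,total_COPs,10,1,0.94,0.01,percent_of_initial,total-cops-table
control_no_quercetin,total_COPs,30,1,5.94,0.05,percent_of_initial,total-cops-table
control_no_quercetin,total_COPs,60,1,15.4,0.3,percent_of_initial,total-cops-table
control_no_quercetin,total_COPs,90,1,30.9,0.5,percent_of_initial,total-cops-table
with_quercetin,total_COPs,0,1,0.07,0.00,percent_of_initial,total-cops-table
with_quercetin,total_COPs,5,1,0.09,0.00,percent_of_initial,total-cops-table
with_quercetin,total_COPs,10,1,0.16,0.01,percent_of_initial,total-cops-table
with_quercetin,total_COPs,30,1,0.51,0.00,percent_of_initial,total-cops-table
with_quercetin,total_COPs,60,1,2.05,0.03,percent_of_initial,total-cops-table
with_quercetin,total_COPs,90,1,7.77,0.06,percent_of_initial,total-cops-table
with_quercetin,total_COPs,120,1,24.4,0.4,percent_of_initial,total-cops-table
control_no_quercetin,cholesterol,0,1,97.9,0.6,percent_of_initial,residual-cholesterol-table
control_no_quercetin,cholesterol,5,1,93.2,1.05,percent_of_initial,residual-cholesterol-table
control_no_quercetin,cholesterol,10,1,87.5,0.4,percent_of_initial,residual-cholesterol-table
control_no_quercetin,cholesterol,30,1,69.0,1.0,percent_of_initial,residual-cholesterol-table
control_no_quercetin,cholesterol,60,1,64.2,0.9,percent_of_initial,residual-cholesterol-table
control_no_quercetin,cholesterol,90,1,66.4,0.7,percent_of_initial,residual-cholesterol-table
with_quercetin,cholesterol,0,1,96.9,0.3,percent_of_initial,residual-cholesterol-table
with_quercetin,cholesterol,5,1,95.7,0.2,percent_of_initial,residual-cholesterol-table
with_quercetin,cholesterol,10,1,94.1,0.1,percent_of_initial,residual-cholesterol-table
with_quercetin,cholesterol,30,1,86.4,0.1,percent_of_initial,residual-cholesterol-table
with_quercetin,cholesterol,60,1,80.5,0.3,percent_of_initial,residual-cholesterol-table
with_quercetin,cholesterol,90,1,77.1,0.5,percent_of_initial,residual-cholesterol-table
with_quercetin,cholesterol,120,1,77.4,2.4,percent_of_initial,residual-cholesterol-table
control_no_quercetin,hydroperoxide_7OOH,0,1,0.82,,mg_per_100g_cholesterol,hydroperoxide-points
control_no_quercetin,hydroperoxide_7OOH,10,1,3.7,,mg_per_100g_cholesterol,hydroperoxide-points
control_no_quercetin,hydroperoxide_7OOH,30,1,18.0,,mg_per_100g_cholesterol,hydroperoxide-points
with_quercetin,hydroperoxide_7OOH,0,1,0.13,,mg_per_100g_cholesterol,hydroperoxide-points
with_quercetin,hydroperoxide_7OOH,10,1,0.82,,mg_per_100g_cholesterol,hydroperoxide-points
with_quercetin,hydroperoxide_7OOH,30,1,2.6,,mg_per_100g_cholesterol,hydroperoxide-points
control_no_quercetin,epoxide_56EP,0,1,0.44,,mg_per_100g_cholesterol,epoxide-points
control_no_quercetin,epoxide_56EP,10,1,3.2,,mg_per_100g_cholesterol,epoxide-points
control_no_quercetin,epoxide_56EP,30,1,17.7,,mg_per_100g_cholesterol,epoxide-points
with_quercetin,epoxide_56EP,0,1,0.46,,mg_per_100g_cholesterol,epoxide-points
with_quercetin,epoxide_56EP,10,1,1.00,,mg_per_100g_cholesterol,epoxide-points
with_quercetin,epoxide_56EP,30,1,2.83,,mg_per_100g_cholesterol,epoxide-points
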