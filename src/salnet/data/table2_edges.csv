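region_a,region_b,fiber_type,left_n,left_mean_present,left_mean_all,right_n,right_mean_present,right_mean_all,li,p
a24pr,a32pr,U_fiber,25,1246.72,1246.72,25,1216,1216,-0.01,0.97
a24pr,AVI,FAT,3,16.67,2,0,0,0,-1.00,
a24pr,FOP4,FAT,3,56.67,6.8,2,125,10,0.19,0.72
a24pr,FOP5,FAT,3,57.33,6.88,2,22,1.76,-0.59,0.39
a24pr,MI,FAT,1,4,0.16,1,222,8.88,0.96,0.33
a24pr,p32pr,U_fiber,25,1278.96,1278.96,25,2017.68,2017.68,0.22,0.29
a24pr,SCEF,U_fiber,12,262.33,125.92,10,597.4,238.96,0.31,0.54
a24pr,46,Other,3,224.67,26.96,3,111.33,13.36,-0.34,0.29
a32pr,AVI,FAT,4,55,8.8,1,226,9.04,0.01,0.98
a32pr,FOP4,FAT,6,13.67,3.28,5,34.8,6.96,0.36,0.42
a32pr,FOP5,FAT,6,144.67,34.72,3,4,0.48,-0.97,0.09
a32pr,MI,FAT,1,20,0.8,1,14,0.56,-0.18,0.81
a32pr,p32pr,U_fiber,2,1164.4,1164.4,25,3688.8,3688.8,0.52,0.33
a32pr,SCEF,U_fiber,23,290.96,267.68,13,1898.62,987.28,0.57,0.22
a32pr,46,Other,8,431.25,138,7,189.43,53.04,-0.44,0.52
AVI,FOP4,U_fiber,22,235.82,207.52,22,469.55,413.2,0.33,0.23
AVI,FOP5,U_fiber,25,744.08,744.08,24,1614.92,1550.32,0.35,0.34
AVI,MI,U_fiber,24,497.67,477.76,24,837.33,803.84,0.25,0.45
AVI,p32pr,FAT,5,16.4,3.28,2,117,9.36,0.48,0.50
AVI,SCEF,FAT,2,86,6.88,0,0,0,-1.00,
AVI,46,Other,5,146,29.2,3,706,84.72,0.49,0.51
FOP4,FOP5,U_fiber,25,1160.8,1160.8,25,1341.28,1341.28,0.07,0.80
FOP4,MI,U_fiber,25,1511.92,1511.92,25,1601.92,1601.92,0.03,0.95
FOP4,p32pr,FAT,15,262,157.2,5,102,20.4,-0.77,0.17
FOP4,SCEF,FAT,16,457.63,292.88,7,668.29,187.12,-0.22,0.52
FOP4,46,Other,6,262,62.88,9,965.33,347.52,0.69,0.31
FOP5,MI,U_fiber,22,636.36,560,20,901.4,721.12,0.13,0.78
FOP5,p32pr,FAT,5,22.8,4.56,3,34.67,4.16,-0.05,0.93
FOP5,SCEF,FAT,6,82,19.68,1,6,0.24,-0.98,0.08
FOP5,46,Other,5,414.4,82.88,9,935.56,336.8,0.61,0.34
MI,p32pr,FAT,4,23.5,3.76,1,4,0.16,-0.92,0.17
MI,SCEF,FAT,9,68.44,24.64,4,21,3.36,-0.76,0.13
MI,46,Other,3,406,48.72,3,880,105.6,0.37,0.62
p32pr,SCEF,U_fiber,25,2138.72,2138.72,25,2915.84,2915.84,0.15,0.43
p32pr,46,Other,6,43.67,10.48,3,532.67,63.92,0.72,0.24
SCEF,46,Other,11,70.55,31.04,3,114.67,13.76,-0.39,0.39
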